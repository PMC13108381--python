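"""Small cohort-level summaries (incidence rates, fold changes)."""

from __future__ import annotations

__all__ = ["incidence_percent", "fold_change"]


def incidence_percent(affected: int, total: int) -> float:
    """Percentage of a cohort showing a phenotype (100 x affected / total)."""
    if total <= 0:
        raise ValueError("cohort size must be positive")
    if not 0 <= affected <= total:
        raise ValueError("affected count must lie in [0, total]")
    return 100.0 * affected / total


def fold_change(value: float, reference: float) -> float:
    """value / reference; the reference must be non-zero."""
    if reference == 0:
        raise ValueError("reference is zero; fold change undefined")
    return value / reference
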