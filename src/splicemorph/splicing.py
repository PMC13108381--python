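"""Exon inclusion proportion (EIP) analysis from splice-junction reads.

A transcript that includes a cassette exon contributes two junction-spanning
reads' worth of evidence (one junction on each flank), while a skipping
transcript contributes a single exclusion junction. The per-cell inclusion
proportion therefore doubles the exclusion count in its denominator:

    EIP = I / (I + 2 E)

where I counts reads over either inclusion junction and E reads over the
skipping junction. Exons with alternative 5'/3' splice sites within one exon
(variant pairs such as 23a/23b) share their exclusion junction and are
treated as mutually exclusive:

    EIP_a = I_a / (I_a + I_b + E),   EIP_b analogous,  EIP_a + EIP_b <= 1.

Subclass-level summaries, the cross-subclass variance decomposition, and a
centered unscaled PCA over subclass splicing profiles live here as well,
together with the coding-impact arithmetic for in-frame cassette exons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "Junction",
    "ExonEvent",
    "load_exon_table",
    "read_sj_tab",
    "compute_eip",
    "compute_variant_eip",
    "detection_gate",
    "cell_eip_table",
    "aggregate_by_subclass",
    "splicing_variation",
    "pca_embed",
    "exon_coding_impact",
]

SJ_COLUMNS = [
    "chrom",
    "intron_start",
    "intron_end",
    "strand",
    "motif",
    "annotated",
    "unique_reads",
    "multi_reads",
    "max_overhang",
]


@dataclass(frozen=True)
class Junction:
    """A splice junction in SJ.out.tab coordinates.

    ``start`` and ``end`` are 1-based first and last intronic bases.
    ``strand`` follows the SJ.out.tab encoding: 0 undefined, 1 = ``+``,
    2 = ``-``.
    """

    chrom: str
    start: int
    end: int
    strand: int = 0

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("junction coordinates must be strictly ordered")


@dataclass
class ExonEvent:
    """Annotation of one cassette-exon event.

    ``inclusion`` lists the junctions flanking the exon (normally two);
    ``exclusion`` the skipping junction(s). ``variant_group`` names the set
    of mutually exclusive splice-site variants this event belongs to, if any
    (e.g. events ``"23a"`` and ``"23b"`` share group ``"23"``).
    """

    gene: str
    event: str
    inclusion: list = field(default_factory=list)
    exclusion: list = field(default_factory=list)
    variant_group: str | None = None
    sequence: str | None = None


def load_exon_table() -> pd.DataFrame:
    """Packaged table of alternatively spliced latrophilin exon sequences.

    Columns: gene (Adgrl1-3), exon label, nucleotide sequence.
    """
    ref = resources.files("splicemorph.data") / "adgrl_exons.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", dtype={"exon": str})


def read_sj_tab(
    path,
    annotation: list[ExonEvent],
    cell: str = "cell0",
    match_strand: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign SJ.out.tab unique-read counts to annotated exon events.

    Returns a per-cell long table (cell, event, I, E) covering every
    annotated event, plus a side table of junction rows that matched no
    annotation (counts preserved, never silently dropped). Only unique
    reads are counted; multi-mapping junction reads are ignored.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise ValueError(
                    f"{path}: line {lineno}: expected 9 columns, "
                    f"got {len(parts)}"
                )
            try:
                rows.append(
                    (
                        parts[0],
                        int(parts[1]),
                        int(parts[2]),
                        int(parts[3]),
                        int(parts[4]),
                        int(parts[5]),
                        int(parts[6]),
                        int(parts[7]),
                        int(parts[8]),
                    )
                )
            except ValueError as err:
                raise ValueError(
                    f"{path}: line {lineno}: malformed field ({err})"
                ) from None
    sj = pd.DataFrame(rows, columns=SJ_COLUMNS)

    def key(chrom, start, end, strand):
        return (chrom, start, end, strand if match_strand else None)

    counts: dict[tuple, int] = {}
    for _, r in sj.iterrows():
        k = key(r.chrom, r.intron_start, r.intron_end, r.strand)
        counts[k] = counts.get(k, 0) + int(r.unique_reads)

    matched_keys = set()
    out = []
    for ev in annotation:
        i_reads = 0
        for j in ev.inclusion:
            k = key(j.chrom, j.start, j.end, j.strand)
            i_reads += counts.get(k, 0)
            matched_keys.add(k)
        e_reads = 0
        for j in ev.exclusion:
            k = key(j.chrom, j.start, j.end, j.strand)
            e_reads += counts.get(k, 0)
            matched_keys.add(k)
        out.append((cell, ev.event, i_reads, e_reads))
    table = pd.DataFrame(out, columns=["cell", "event", "I", "E"])

    unmatched_mask = [
        key(r.chrom, r.intron_start, r.intron_end, r.strand)
        not in matched_keys
        for _, r in sj.iterrows()
    ]
    side = sj[unmatched_mask].reset_index(drop=True) if len(sj) else sj
    return table, side


def compute_eip(I, E):
    """EIP = I / (I + 2E); NaN (missing) where I = E = 0.

    Accepts scalars or arrays; inputs must be non-negative.
    """
    I = np.asarray(I, dtype=float)
    E = np.asarray(E, dtype=float)
    if (I < 0).any() or (E < 0).any():
        raise ValueError("junction read counts must be non-negative")
    denom = I + 2.0 * E
    with np.errstate(invalid="ignore", divide="ignore"):
        eip = np.where(denom > 0, I / denom, np.nan)
    if eip.ndim == 0:
        return float(eip)
    return eip


def compute_variant_eip(I_a, I_b, E):
    """Mutually exclusive splice-site variants sharing one exclusion junction.

    EIP_a = I_a / (I_a + I_b + E) and likewise for b, so the two proportions
    sum to at most 1. Returns (EIP_a, EIP_b); both NaN when all counts are 0.
    """
    I_a = np.asarray(I_a, dtype=float)
    I_b = np.asarray(I_b, dtype=float)
    E = np.asarray(E, dtype=float)
    if (I_a < 0).any() or (I_b < 0).any() or (E < 0).any():
        raise ValueError("junction read counts must be non-negative")
    denom = I_a + I_b + E
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(denom > 0, I_a / denom, np.nan)
        b = np.where(denom > 0, I_b / denom, np.nan)
    if a.ndim == 0:
        return float(a), float(b)
    return a, b


def detection_gate(
    table: pd.DataFrame,
    cell_totals: pd.Series,
    threshold: float = 1.0,
) -> pd.Series:
    """Minimal-detection gate for (cell, event) pairs.

    A pair is analyzable iff the inclusion *or* exclusion junction reads
    reach a CPM (against the cell's total mapped reads) with
    log2(CPM + 1) strictly above ``threshold``. The boundary case
    log2(CPM + 1) == threshold fails.
    """
    totals = cell_totals.reindex(table["cell"]).to_numpy(dtype=float)
    if (totals <= 0).any() or np.isnan(totals).any():
        raise ValueError("cell totals must be positive for all table cells")
    cpm_i = table["I"].to_numpy(dtype=float) / totals * 1e6
    cpm_e = table["E"].to_numpy(dtype=float) / totals * 1e6
    passes = (np.log2(cpm_i + 1) > threshold) | (np.log2(cpm_e + 1) > threshold)
    return pd.Series(passes, index=table.index, name="detected")


def cell_eip_table(
    table: pd.DataFrame,
    cell_totals: pd.Series | None = None,
    threshold: float = 1.0,
) -> pd.DataFrame:
    """Per-cell EIPs with the detection gate applied.

    Adds ``eip`` and ``detected`` columns; gated-out or uncovered pairs get
    NaN EIP. When ``cell_totals`` is None no gate is applied.
    """
    out = table.copy()
    out["eip"] = compute_eip(out["I"].to_numpy(), out["E"].to_numpy())
    if cell_totals is not None:
        out["detected"] = detection_gate(out, cell_totals, threshold)
        out.loc[~out["detected"], "eip"] = np.nan
    else:
        out["detected"] = out["eip"].notna()
    return out


def aggregate_by_subclass(
    cell_eips: pd.DataFrame,
    labels: pd.Series,
    min_cells: int = 100,
    mode: str = "mean",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Subclass x event EIP summary.

    ``mode="mean"`` averages per-cell EIPs over cells with a defined,
    gate-passing EIP (the default; EIP is defined per cell). ``mode="pooled"``
    instead pools junction reads over those cells and applies the EIP
    formula once. Subclasses with at most ``min_cells`` total cells are
    dropped entirely (the analysis requires >min_cells cells).

    Returns (eip matrix, contributing-cell counts), both subclass x event.
    """
    if mode not in ("mean", "pooled"):
        raise ValueError("mode must be 'mean' or 'pooled'")
    df = cell_eips.copy()
    df["subclass"] = labels.reindex(df["cell"]).to_numpy()
    if df["subclass"].isna().any():
        raise ValueError("labels missing for some cells")
    sizes = labels.value_counts()
    big = sizes[sizes > min_cells].index
    df = df[df["subclass"].isin(big)]
    usable = df[df["eip"].notna()]
    n_cells = (
        usable.pivot_table(
            index="subclass", columns="event", values="cell", aggfunc="count"
        )
        .fillna(0)
        .astype(int)
    )
    if mode == "mean":
        eip = usable.pivot_table(
            index="subclass", columns="event", values="eip", aggfunc="mean"
        )
    else:
        pooled = usable.groupby(["subclass", "event"])[["I", "E"]].sum()
        pooled["eip"] = compute_eip(
            pooled["I"].to_numpy(), pooled["E"].to_numpy()
        )
        eip = pooled["eip"].unstack("event")
    return eip, n_cells.reindex_like(eip).fillna(0).astype(int)


def splicing_variation(
    subclass_eip: pd.DataFrame,
    gene_of_event: pd.Series | dict,
) -> dict:
    """Cross-subclass splicing variance per event, per gene, and per family.

    Variance is the population variance (SD squared, ddof=0) of the
    subclass EIPs of each event, complete-case over subclasses with a
    defined value. Events observed in fewer than two subclasses are skipped
    with a warning. Gene totals sum their events; family fractions divide
    each gene total by the family-wide sum (and sum to 1).
    """
    gene_of_event = pd.Series(gene_of_event)
    per_event = {}
    for event in subclass_eip.columns:
        vals = subclass_eip[event].dropna().to_numpy(dtype=float)
        if vals.size < 2:
            warnings.warn(
                f"event {event!r}: <2 subclasses with data, skipped",
                stacklevel=2,
            )
            continue
        per_event[event] = float(np.var(vals))  # ddof=0
    event_var = pd.Series(per_event, name="variance")
    genes = gene_of_event.reindex(event_var.index)
    gene_var = event_var.groupby(genes).sum()
    total = gene_var.sum()
    family_fraction = gene_var / total if total > 0 else gene_var * np.nan
    return {
        "event_variance": event_var,
        "gene_variance": gene_var,
        "family_fraction": family_fraction,
    }


@dataclass
class EIPEmbedding:
    """Centered, unscaled PCA of subclass splicing profiles."""

    scores: pd.DataFrame  # subclasses x components
    loadings: pd.DataFrame  # events x components
    explained_variance_ratio: np.ndarray
    column_means: pd.Series
    degenerate: bool = False


def pca_embed(subclass_eip: pd.DataFrame, n_components: int | None = None) -> EIPEmbedding:
    """PCA on a complete subclass x event EIP matrix.

    Columns (events) are centered but not scaled. Missing entries are a
    hard error: gate events/subclasses to a complete matrix first. The sign
    of each component is fixed by making its largest-magnitude loading
    positive, so outputs are reproducible. A matrix with zero total
    variance is flagged degenerate.
    """
    X = subclass_eip.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError(
            "EIP matrix contains missing values; apply detection/cell-count "
            "gates (or drop incomplete events) before PCA"
        )
    mu = X.mean(axis=0)
    Xc = X - mu
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(len(s), n_components or len(s))
    total = float((s**2).sum())
    degenerate = total <= 0
    ratios = (s[:k] ** 2) / total if not degenerate else np.full(k, np.nan)
    # deterministic sign: largest-|loading| entry of each component positive
    for j in range(k):
        i_max = np.argmax(np.abs(vt[j]))
        if vt[j, i_max] < 0:
            vt[j] = -vt[j]
            u[:, j] = -u[:, j]
    scores = u[:, :k] * s[:k]
    comp_names = [f"PC{j + 1}" for j in range(k)]
    return EIPEmbedding(
        scores=pd.DataFrame(
            scores, index=subclass_eip.index, columns=comp_names
        ),
        loadings=pd.DataFrame(
            vt[:k].T, index=subclass_eip.columns, columns=comp_names
        ),
        explained_variance_ratio=np.asarray(ratios),
        column_means=pd.Series(mu, index=subclass_eip.columns),
        degenerate=degenerate,
    )


def exon_coding_impact(sequence: str) -> tuple[int, bool, int | None]:
    """Coding arithmetic for a cassette exon sequence.

    Returns (length in nt, length divisible by three, encoded amino acids).
    An exon whose length is a multiple of three inserts length/3 residues
    without shifting the downstream reading frame; otherwise the amino-acid
    count is None.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    seq = sequence.upper()
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"non-ACGT characters in sequence: {sorted(bad)}")
    n = len(seq)
    in_frame = n % 3 == 0
    return n, in_frame, n // 3 if in_frame else None
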