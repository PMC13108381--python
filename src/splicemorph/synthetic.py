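"""Synthetic benchmark generators with known ground truth.

Every downstream stage of the pipeline is exercised against data generated
here: junction reads drawn under a per-subclass inclusion probability,
negative-binomial gene counts with subclass-specific means, rendered 2D
vessel networks with analytic geometry, 3D tube-plus-puncta volumes with
known surface distances, and linear standard-curve plate readings.

The junction simulator draws each read as an inclusion-junction read with
probability 2*psi / (1 + psi): a transcript that includes the exon presents
two junctions, a skipping transcript one, which is exactly why the EIP
denominator doubles the exclusion count. Under this read model the EIP
estimator I / (I + 2E) is unbiased for psi by construction.

All generators take an integer seed; sub-streams are derived per named
stage so a stage can be regenerated in isolation (see :func:`stream`).
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
import yaml

from .expression import CellCounts

__all__ = [
    "stream",
    "SplicingTruth",
    "simulate_junction_reads",
    "simulate_expression_matrix",
    "VesselGroundTruth",
    "render_vessel_image",
    "ContactVolumeTruth",
    "make_contact_truth",
    "render_contact_volume",
    "generate_standard_curve_data",
    "write_counts_mtx",
    "write_sj_tab",
    "write_calibrated_tiff",
    "write_truth_json",
]


def stream(seed: int, label: str) -> np.random.Generator:
    """Independent random stream derived from one global seed and a label."""
    key = zlib.crc32(label.encode())
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


def _negative_binomial(
    rng: np.random.Generator, mean, dispersion: float, size=None
):
    """NB draws parameterized by mean and dispersion (shape) parameter.

    Variance is mean + mean^2 / dispersion; dispersion = inf recovers
    Poisson (used directly when dispersion is None or infinite).
    """
    mean = np.asarray(mean, dtype=float)
    if dispersion is None or np.isinf(dispersion):
        return rng.poisson(mean, size=size)
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    # gamma-Poisson mixture; robust for non-integer dispersion
    lam = rng.gamma(dispersion, mean / dispersion, size=size)
    return rng.poisson(lam)


# ---------------------------------------------------------------------------
# splicing / expression
# ---------------------------------------------------------------------------


@dataclass
class SplicingTruth:
    """Generative ground truth for junction-read simulation.

    ``psi`` is the true exon inclusion proportion per event per subclass
    (events x subclasses DataFrame, values in [0, 1]) — the quantity the
    EIP estimator should recover. ``mean_depth``/``dispersion`` set the
    negative-binomial junction coverage per cell and event.
    """

    psi: pd.DataFrame
    cells_per_subclass: int | dict = 200
    mean_depth: float = 50.0
    dispersion: float = 5.0
    mean_total_reads: float = 5e5
    seed: int = 0

    def __post_init__(self) -> None:
        vals = self.psi.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise ValueError("psi must be finite")
        if (vals < 0).any() or (vals > 1).any():
            raise ValueError("psi must lie in [0, 1]")
        if self.mean_depth <= 0:
            raise ValueError("mean depth must be positive")
        n = self.cells_per_subclass
        counts = (
            n.values() if isinstance(n, dict) else [n]
        )
        if any(c < 1 for c in counts):
            raise ValueError("cells per subclass must be >= 1")

    def n_cells(self, subclass: str) -> int:
        if isinstance(self.cells_per_subclass, dict):
            return int(self.cells_per_subclass[subclass])
        return int(self.cells_per_subclass)


def simulate_junction_reads(
    truth: SplicingTruth,
) -> tuple[pd.DataFrame, CellCounts]:
    """Draw per-cell inclusion/exclusion junction reads under ``truth``.

    For each cell and event, coverage N is negative-binomial
    (``mean_depth``, ``dispersion``); each of the N reads is an
    inclusion-junction read with probability 2*psi/(1+psi), else an
    exclusion read. Returns the long junction table (cell, event, I, E)
    and a small matching gene-count matrix (with per-cell totals drawn
    lognormally around ``mean_total_reads``) so CPM-based gates can be
    exercised end to end.
    """
    rng = stream(truth.seed, "junction-reads")
    rows = []
    cells = []
    labels = []
    for subclass in truth.psi.columns:
        for i in range(truth.n_cells(subclass)):
            cell = f"{subclass}_{i}"
            cells.append(cell)
            labels.append(subclass)
            for event in truth.psi.index:
                psi = float(truth.psi.loc[event, subclass])
                n = int(
                    _negative_binomial(
                        rng, truth.mean_depth, truth.dispersion
                    )
                )
                p_incl = 2.0 * psi / (1.0 + psi)
                inc = int(rng.binomial(n, p_incl)) if n else 0
                rows.append((cell, event, inc, n - inc))
    table = pd.DataFrame(rows, columns=["cell", "event", "I", "E"])

    totals = pd.Series(
        np.round(
            rng.lognormal(np.log(truth.mean_total_reads), 0.3, len(cells))
        ).astype(int),
        index=pd.Index(cells, name="cell"),
    )
    # a handful of uniformly expressed genes; totals come from the aligner
    gene_cpm = np.array([500.0, 200.0, 50.0])
    counts = pd.DataFrame(
        _negative_binomial(
            rng,
            gene_cpm[:, None] * totals.to_numpy()[None, :] / 1e6,
            truth.dispersion,
        ),
        index=[f"gene{i}" for i in range(len(gene_cpm))],
        columns=cells,
    )
    matrix = CellCounts(
        counts=counts,
        labels=pd.Series(labels, index=cells),
        totals=totals,
    )
    return table, matrix


def _calibrated_cpm(
    mu: float, median_lib: float, dispersion: float | None
) -> float:
    """Linear CPM whose expected mean log2(CPM+1) under the count noise
    equals ``mu``.

    Counts are discrete and the mean of a log falls below the log of a
    mean, so drawing counts around 2^mu - 1 would systematically undershoot
    the requested log-scale profile. This inverts that gap numerically
    (bisection on a monotone expectation, Poisson/NB pmf summation).
    """
    from scipy import stats as sps

    if mu <= 0:
        return 0.0

    def expected_log(cpm: float) -> float:
        mean_count = cpm * median_lib / 1e6
        hi = int(mean_count + 12 * np.sqrt(mean_count + mean_count**2 /
                 (dispersion or np.inf)) + 12)
        k = np.arange(hi + 1)
        if dispersion is None or np.isinf(dispersion):
            pmf = sps.poisson.pmf(k, mean_count)
        else:
            p = dispersion / (dispersion + mean_count)
            pmf = sps.nbinom.pmf(k, dispersion, p)
        return float((pmf * np.log2(k * 1e6 / median_lib + 1.0)).sum())

    lo, hi = 2.0**mu - 1.0, (2.0**mu - 1.0) * 4 + 4
    while expected_log(hi) < mu:
        hi *= 2
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if expected_log(mid) < mu:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-9 * max(hi, 1.0):
            break
    return 0.5 * (lo + hi)


def simulate_expression_matrix(
    subclass_means: pd.DataFrame,
    dispersion: float = 20.0,
    cells_per_subclass: int | dict = 200,
    mean_total_reads: float = 1e6,
    seed: int = 0,
) -> CellCounts:
    """Negative-binomial count matrix with subclass-specific mean expression.

    ``subclass_means`` gives the target mean log2(CPM+1) per gene per
    subclass (genes x subclasses). Per-cell library sizes vary lognormally
    around ``mean_total_reads``; the count mean for each gene/subclass is
    calibrated (see :func:`_calibrated_cpm`) so the subclass mean
    log-expression recovers the requested profile within sampling error
    rather than undershooting it by the log-of-mean / mean-of-log gap.
    """
    mu = subclass_means.to_numpy(dtype=float)
    if (mu < 0).any():
        raise ValueError("mean log2(CPM+1) values must be non-negative")
    if dispersion is not None and dispersion <= 0:
        raise ValueError("dispersion must be positive")
    rng = stream(seed, "expression-matrix")
    target_cpm = np.array(
        [
            [_calibrated_cpm(m, mean_total_reads, dispersion) for m in row]
            for row in mu
        ]
    )
    cells, labels, cols, libs = [], [], [], []
    for k, subclass in enumerate(subclass_means.columns):
        n = (
            cells_per_subclass[subclass]
            if isinstance(cells_per_subclass, dict)
            else cells_per_subclass
        )
        lib = np.round(
            rng.lognormal(np.log(mean_total_reads), 0.3, int(n))
        ).astype(int)
        mean_counts = target_cpm[:, [k]] * lib[None, :] / 1e6
        block = _negative_binomial(rng, mean_counts, dispersion)
        cols.append(block)
        names = [f"{subclass}_{i}" for i in range(int(n))]
        cells.extend(names)
        labels.extend([subclass] * int(n))
        libs.extend(lib.tolist())
    counts = pd.DataFrame(
        np.concatenate(cols, axis=1),
        index=subclass_means.index,
        columns=cells,
    )
    # totals are the simulated library sizes (the matrix holds only the
    # genes of interest, not the whole transcriptome)
    return CellCounts(
        counts=counts,
        labels=pd.Series(labels, index=cells),
        totals=pd.Series(libs, index=cells, dtype=float),
    )


# ---------------------------------------------------------------------------
# 2D vessel rendering
# ---------------------------------------------------------------------------


@dataclass
class VesselGroundTruth:
    """A 2D vessel network as line segments with widths, plus derived truth.

    ``segments`` are ((x0, y0), (x1, y1), width) triples in micrometres,
    in image coordinates (x rightwards, y downwards). Derived quantities —
    total centerline length, branch points (where >= 3 segment endpoints
    coincide), length-weighted mean width — are consistent with the
    segments by construction.
    """

    segments: list
    shape_um: tuple = (200.0, 200.0)  # (height, width)
    pixel_size: float = 0.5
    noise_sd: float = 0.0
    background_amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel size must be positive")
        h, w = self.shape_um
        for (x0, y0), (x1, y1), width in self.segments:
            if width <= 0:
                raise ValueError("segment widths must be positive")
            for x, y in ((x0, y0), (x1, y1)):
                if not (0 <= x <= w and 0 <= y <= h):
                    raise ValueError("segment endpoints must lie in bounds")

    @property
    def total_length(self) -> float:
        return float(
            sum(
                np.hypot(x1 - x0, y1 - y0)
                for (x0, y0), (x1, y1), _ in self.segments
            )
        )

    @property
    def mean_width(self) -> float:
        if not self.segments:
            return float("nan")
        lengths = np.array(
            [
                np.hypot(x1 - x0, y1 - y0)
                for (x0, y0), (x1, y1), _ in self.segments
            ]
        )
        widths = np.array([w for *_, w in self.segments])
        return float((lengths * widths).sum() / lengths.sum())

    @property
    def branch_points(self) -> list:
        """Coordinates where three or more segment endpoints meet."""
        pts: dict[tuple, int] = {}
        for (x0, y0), (x1, y1), _ in self.segments:
            for p in ((round(x0, 6), round(y0, 6)), (round(x1, 6), round(y1, 6))):
                pts[p] = pts.get(p, 0) + 1
        return [p for p, c in pts.items() if c >= 3]


def _segment_distance_grid(shape, pixel_size, seg):
    """Distance (um) from each pixel center to a segment."""
    (x0, y0), (x1, y1), _ = seg
    ny, nx = shape
    ys = (np.arange(ny) + 0.5) * pixel_size
    xs = (np.arange(nx) + 0.5) * pixel_size
    X, Y = np.meshgrid(xs, ys)
    dx, dy = x1 - x0, y1 - y0
    L2 = dx * dx + dy * dy
    if L2 == 0:
        return np.hypot(X - x0, Y - y0)
    t = np.clip(((X - x0) * dx + (Y - y0) * dy) / L2, 0.0, 1.0)
    return np.hypot(X - (x0 + t * dx), Y - (y0 + t * dy))


def render_vessel_image(
    truth: VesselGroundTruth,
) -> tuple[np.ndarray, np.ndarray]:
    """Render a vessel network to a grayscale image plus its truth mask.

    Tubes are anti-aliased over one pixel at their edges; optional additive
    Gaussian noise and a smooth low-frequency background gradient emulate
    acquisition artefacts. The noiseless truth mask marks pixels whose
    center lies within half a width of a centerline.
    """
    ny = int(round(truth.shape_um[0] / truth.pixel_size))
    nx = int(round(truth.shape_um[1] / truth.pixel_size))
    image = np.zeros((ny, nx), dtype=float)
    mask = np.zeros((ny, nx), dtype=bool)
    for seg in truth.segments:
        d = _segment_distance_grid((ny, nx), truth.pixel_size, seg)
        half = seg[2] / 2.0
        profile = np.clip((half - d) / truth.pixel_size + 0.5, 0.0, 1.0)
        image = np.maximum(image, profile)
        mask |= d <= half
    rng = stream(truth.seed, "vessel-image")
    if truth.background_amplitude > 0:
        ys = np.linspace(0, 1, ny)[:, None]
        xs = np.linspace(0, 1, nx)[None, :]
        phase = rng.uniform(0, 2 * np.pi, 2)
        background = 0.5 * (
            np.sin(2 * np.pi * ys + phase[0])
            + np.cos(2 * np.pi * xs + phase[1])
        )
        image = image + truth.background_amplitude * (background + 1.0) / 2.0
    if truth.noise_sd > 0:
        image = image + rng.normal(0.0, truth.noise_sd, image.shape)
    return np.clip(image, 0.0, None), mask


# ---------------------------------------------------------------------------
# 3D contact volumes
# ---------------------------------------------------------------------------


@dataclass
class ContactVolumeTruth:
    """A straight 3D vessel tube plus puncta at known surface distances.

    The tube runs along the y axis at (``axis_x``, ``axis_z``) with radius
    ``radius_um``. ``puncta`` is a list of dicts with keys ``center``
    ((x, y, z) um), ``distance`` (signed distance to the tube surface, um;
    negative inside) and ``amplitude``. Voxel sizes are (x, y, z) um and may
    be anisotropic.
    """

    shape_um: tuple = (20.0, 40.0, 20.0)  # (x, y, z) extent
    axis_x: float = 10.0
    axis_z: float = 10.0
    radius_um: float = 4.0
    voxel_size: tuple = (0.2, 0.2, 0.5)
    puncta: list = field(default_factory=list)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")
        for p in self.puncta:
            x, y, z = p["center"]
            sx, sy, sz = self.shape_um
            if not (0 <= x <= sx and 0 <= y <= sy and 0 <= z <= sz):
                raise ValueError(f"punctum outside volume: {p['center']}")
            geo = self.surface_distance(p["center"])
            if abs(geo - p["distance"]) > 1e-6:
                raise ValueError(
                    "stored punctum distance inconsistent with geometry: "
                    f"{p['distance']} vs {geo}"
                )

    def surface_distance(self, center) -> float:
        """Signed distance from a point to the tube surface (um)."""
        x, _, z = center
        return float(np.hypot(x - self.axis_x, z - self.axis_z) - self.radius_um)


def make_contact_truth(
    distances,
    amplitudes=None,
    spacing_um: float = 4.0,
    **kwargs,
) -> ContactVolumeTruth:
    """Place puncta at requested signed surface distances along the tube.

    Puncta are positioned on the +x side of the tube, spaced ``spacing_um``
    apart along y, so stored distances equal geometric distances exactly.
    """
    truth = ContactVolumeTruth(puncta=[], **kwargs)
    amplitudes = amplitudes or [1.0] * len(distances)
    puncta = []
    for i, (d, a) in enumerate(zip(distances, amplitudes)):
        x = truth.axis_x + truth.radius_um + d
        y = spacing_um * (i + 1)
        puncta.append(
            {"center": (x, y, truth.axis_z), "distance": float(d), "amplitude": a}
        )
    return ContactVolumeTruth(puncta=puncta, **kwargs)


def render_contact_volume(
    truth: ContactVolumeTruth,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render (tube channel, puncta channel, tube mask), arrays in (z, y, x).

    Channel 1 carries the surface marker (soft-edged tube), channel 2
    Gaussian puncta (sigma 0.3 um lateral, 0.6 um axial) at the specified
    centers. Anisotropic voxel sizes are honored throughout.
    """
    vx, vy, vz = truth.voxel_size
    nx = int(round(truth.shape_um[0] / vx))
    ny = int(round(truth.shape_um[1] / vy))
    nz = int(round(truth.shape_um[2] / vz))
    xs = (np.arange(nx) + 0.5) * vx
    ys = (np.arange(ny) + 0.5) * vy
    zs = (np.arange(nz) + 0.5) * vz
    Z, Y, X = np.meshgrid(zs, ys, xs, indexing="ij")
    radial = np.hypot(X - truth.axis_x, Z - truth.axis_z)
    mask = radial <= truth.radius_um
    edge = min(vx, vz)
    tube = np.clip((truth.radius_um - radial) / edge + 0.5, 0.0, 1.0)

    puncta = np.zeros_like(tube)
    sig_lat, sig_ax = 0.3, 0.6
    for p in truth.puncta:
        px, py, pz = p["center"]
        g = np.exp(
            -(
                (X - px) ** 2 / (2 * sig_lat**2)
                + (Y - py) ** 2 / (2 * sig_lat**2)
                + (Z - pz) ** 2 / (2 * sig_ax**2)
            )
        )
        puncta += p.get("amplitude", 1.0) * g
    if truth.noise_sd > 0:
        rng = stream(truth.seed, "contact-volume")
        tube = tube + rng.normal(0, truth.noise_sd, tube.shape)
        puncta = puncta + rng.normal(0, truth.noise_sd, puncta.shape)
    return np.clip(tube, 0, None), np.clip(puncta, 0, None), mask


# ---------------------------------------------------------------------------
# fluorometry
# ---------------------------------------------------------------------------


def generate_standard_curve_data(
    slope: float,
    intercept: float,
    concentrations,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Plate readings from a linear standard curve with Gaussian noise."""
    conc = np.asarray(concentrations, dtype=float)
    if conc.size == 0:
        raise ValueError("need at least one concentration")
    if (conc <= 0).any():
        raise ValueError("concentrations must be positive")
    rng = stream(seed, "standard-curve")
    readings = slope * conc + intercept
    if noise_sd > 0:
        readings = readings + rng.normal(0, noise_sd, conc.shape)
    return pd.DataFrame({"concentration": conc, "reading": readings})


# ---------------------------------------------------------------------------
# writers (plain-text interchange formats)
# ---------------------------------------------------------------------------


def write_counts_mtx(matrix: CellCounts, outdir) -> None:
    """Write counts as MatrixMarket plus genes/barcodes/labels TSVs."""
    from pathlib import Path

    from scipy import io as sio
    from scipy import sparse

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sio.mmwrite(
        str(outdir / "matrix.mtx"),
        sparse.csr_matrix(matrix.counts.to_numpy()),
    )
    (outdir / "genes.tsv").write_text(
        "\n".join(map(str, matrix.counts.index)) + "\n"
    )
    (outdir / "barcodes.tsv").write_text(
        "\n".join(map(str, matrix.counts.columns)) + "\n"
    )
    matrix.labels.rename("subclass").to_csv(
        outdir / "labels.tsv", sep="\t", header=True
    )


def write_sj_tab(table: pd.DataFrame, annotation, path, cell: str) -> None:
    """Write one cell's junction counts in SJ.out.tab column layout."""
    events = {ev.event: ev for ev in annotation}
    lines = []
    sub = table[table["cell"] == cell]
    for _, row in sub.iterrows():
        ev = events[row["event"]]
        n_inc = max(len(ev.inclusion), 1)
        for j in ev.inclusion:
            lines.append(
                f"{j.chrom}\t{j.start}\t{j.end}\t{j.strand}\t0\t1\t"
                f"{int(row['I']) // n_inc}\t0\t30"
            )
        for j in ev.exclusion:
            lines.append(
                f"{j.chrom}\t{j.start}\t{j.end}\t{j.strand}\t0\t1\t"
                f"{int(row['E'])}\t0\t30"
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))


def write_calibrated_tiff(image: np.ndarray, path, pixel_size) -> None:
    """TIFF plus a YAML sidecar holding the um calibration."""
    from pathlib import Path

    path = Path(path)
    tifffile.imwrite(path, np.asarray(image, dtype=np.float32))
    sidecar = path.with_suffix(".yaml")
    if np.isscalar(pixel_size):
        meta = {"pixel_size_um": float(pixel_size)}
    else:
        meta = {"voxel_size_um": [float(v) for v in pixel_size]}
    sidecar.write_text(yaml.safe_dump(meta))


def write_truth_json(truth, path) -> None:
    """Serialize a truth dataclass to JSON."""
    import dataclasses

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.DataFrame):
            return {
                "index": list(o.index),
                "columns": list(o.columns),
                "values": o.to_numpy().tolist(),
            }
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        raise TypeError(type(o))

    with open(path, "w") as fh:
        json.dump(dataclasses.asdict(truth), fh, default=default, indent=1)
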