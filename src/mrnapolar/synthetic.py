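"""Synthetic data generators for every pipeline stage.

Each generator is a pure function of its spec (including the seed) and
returns ground-truth labels alongside the data, so that enrichment
clustering, motif scanning, spot detection / polarisation and the
filopodia-proximity analysis are all exercisable and checkable without any
external download.

What is emulated, and what is not: fold-change tables carry the 2**D
enrichment-status block structure with Gaussian log2 noise and
Beta/uniform p-values (no count-level model); cells are ellipses with von
Mises-polarised or uniform spot patterns (no real cell shapes); images are
isotropic-Gaussian spots on flat background with Poisson or Gaussian noise
(no 3D PSF, drift or photobleaching); time-lapses are reflected random
walks with filopodia born either uniformly in the ROI or from an
exponential proximity kernel around particles.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Sequence

import numpy as np

from .motifs import ALPHABET, PWM
from .proximity import FilopodiumEvent, ParticleTrack, RoiStack
from .spots import CellGeometry, SpotSet, cell_geometry

__all__ = [
    "SimFoldChangeSpec",
    "SimCellSpec",
    "SimTimelapseSpec",
    "SimSequenceSpec",
    "SyntheticImage",
    "gen_foldchange_table",
    "gen_cell_with_spots",
    "render_smfish_image",
    "gen_timelapse",
    "gen_utr_sequences",
    "disk_roi",
]


# ---------------------------------------------------------------- fold changes


@dataclasses.dataclass
class SimFoldChangeSpec:
    """Synthetic protrusion-vs-body fold-change table specification.

    ``status_set`` lists the planted enrichment statuses as tuples of +1
    (enriched) / -1 (depleted), one entry per comparison dataset; the
    default enumerates all 2**D combinations. If ``reference_dataset`` is
    set, an extra reference column is added in which every signal gene is
    enriched (these genes model the ones that passed the reference
    protrusion filter), with p-values drawn Beta(0.1, 1) for signal genes
    and Uniform(0, 1) for nulls, and BH q-values computed over the table.
    ``frac_null_pvalues`` is the fraction of the final table made up of
    null genes (no planted effect anywhere, uniform p).
    """

    n_genes_per_status: int = 50
    comparison_datasets: tuple[str, ...] = ("cellA", "cellB", "cellC")
    status_set: list[tuple[int, ...]] | None = None
    reference_dataset: str | None = "ref"
    effect_log2fc: float = 1.0
    noise_sd: float = 0.2
    frac_null_pvalues: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes_per_status < 1:
            raise ValueError("n_genes_per_status must be >= 1")
        if self.effect_log2fc <= 0:
            raise ValueError("effect_log2fc must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not (0 <= self.frac_null_pvalues < 1):
            raise ValueError("frac_null_pvalues must be in [0, 1)")
        D = len(self.comparison_datasets)
        if self.status_set is None:
            self.status_set = [
                tuple(s)
                for s in np.ndindex(*(2,) * D)
            ]
            self.status_set = [tuple(1 if b == 0 else -1 for b in s) for s in self.status_set]
        for s in self.status_set:
            if len(s) != D:
                raise ValueError(
                    f"status vector {s} has length {len(s)}, expected {D}"
                )
            if any(v not in (-1, 1) for v in s):
                raise ValueError("status entries must be +1 or -1")


def gen_foldchange_table(spec: SimFoldChangeSpec):
    """Generate a per-gene fold-change table plus planted-truth labels.

    Returns ``(table, truth)`` as pandas DataFrames. The table has one
    ``log2fc_<dataset>`` column per dataset (reference first if present) and,
    with a reference, ``p_value`` and ``q_value`` columns. The truth frame
    records each gene's planted status string (e.g. ``"+-+"``) or ``"null"``.
    """
    import pandas as pd

    from .enrichment import bh_fdr

    rng = np.random.default_rng(spec.seed)
    D = len(spec.comparison_datasets)
    n_signal = spec.n_genes_per_status * len(spec.status_set)
    n_null = (
        int(round(spec.frac_null_pvalues / (1 - spec.frac_null_pvalues) * n_signal))
        if spec.frac_null_pvalues > 0
        else 0
    )

    rows_fc = np.zeros((n_signal + n_null, D))
    statuses: list[str] = []
    for i, status in enumerate(spec.status_set):
        block = slice(i * spec.n_genes_per_status, (i + 1) * spec.n_genes_per_status)
        rows_fc[block] = np.asarray(status, dtype=float) * spec.effect_log2fc
        statuses.extend(["".join("+" if v > 0 else "-" for v in status)] * spec.n_genes_per_status)
    statuses.extend(["null"] * n_null)
    rows_fc += rng.normal(0.0, spec.noise_sd, size=rows_fc.shape)

    data = {"gene_id": [f"gene{i:05d}" for i in range(n_signal + n_null)]}
    if spec.reference_dataset is not None:
        ref_fc = np.concatenate(
            [
                spec.effect_log2fc + rng.normal(0.0, spec.noise_sd, size=n_signal),
                rng.normal(0.0, spec.noise_sd, size=n_null),
            ]
        )
        p = np.concatenate(
            [rng.beta(0.1, 1.0, size=n_signal), rng.uniform(0.0, 1.0, size=n_null)]
        )
        data[f"log2fc_{spec.reference_dataset}"] = ref_fc
    for j, name in enumerate(spec.comparison_datasets):
        data[f"log2fc_{name}"] = rows_fc[:, j]
    if spec.reference_dataset is not None:
        data["p_value"] = p
        data["q_value"] = bh_fdr(p)

    table = pd.DataFrame(data)
    truth = pd.DataFrame(
        {"gene_id": data["gene_id"], "status": statuses, "is_null": [s == "null" for s in statuses]}
    )
    return table, truth


# ----------------------------------------------------------------- cell/spots


@dataclasses.dataclass
class SimCellSpec:
    """Elliptical cell with uniformly or von Mises-polarised spots.

    ``polarization_kappa`` is the concentration of a von Mises angular bias
    of spot placement toward ``axis_angle`` (radians, measured from the
    centroid); kappa = 0 gives uniform placement inside the mask. Kappa of
    order 1-5 spans the PI range seen in real polarised cells (roughly
    0-1); kappa ~ 50 pins all spots to one rim sector.
    """

    semi_axes: tuple[float, float] = (20.0, 10.0)  # micrometres
    pixel_size: float = 0.2
    n_spots: int = 200
    polarization_kappa: float = 0.0
    axis_angle: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.n_spots < 0:
            raise ValueError("n_spots must be nonnegative")
        if self.polarization_kappa < 0:
            raise ValueError("polarization_kappa must be nonnegative")
        if min(self.semi_axes) <= 0:
            raise ValueError("semi-axes must be positive")


def _ellipse_mask(semi_axes: tuple[float, float], pixel_size: float) -> np.ndarray:
    a, b = semi_axes
    margin = 2
    w = int(np.ceil(2 * a / pixel_size)) + 2 * margin
    h = int(np.ceil(2 * b / pixel_size)) + 2 * margin
    cx, cy = w / 2 * pixel_size, h / 2 * pixel_size
    cols, rows = np.meshgrid(np.arange(w), np.arange(h))
    x = (cols + 0.5) * pixel_size
    y = (rows + 0.5) * pixel_size
    return ((x - cx) / a) ** 2 + ((y - cy) / b) ** 2 <= 1.0


def gen_cell_with_spots(spec: SimCellSpec) -> tuple[CellGeometry, SpotSet]:
    """Rasterise the cell mask and place spots by rejection sampling.

    Proposals are uniform over mask pixels (plus in-pixel jitter) and are
    accepted with probability exp(kappa * (cos(theta - axis_angle) - 1)),
    where theta is the angle of the proposal about the mask centroid; with
    kappa = 0 every proposal is accepted, giving uniform placement.
    """
    mask = _ellipse_mask(spec.semi_axes, spec.pixel_size)
    geometry = cell_geometry(mask, spec.pixel_size)
    if spec.n_spots == 0:
        return geometry, SpotSet(points=np.empty((0, 2)))
    rng = np.random.default_rng(spec.seed)
    rows, cols = np.nonzero(mask)
    cx, cy = geometry.centroid
    accepted: list[np.ndarray] = []
    while len(accepted) < spec.n_spots:
        m = max(4 * (spec.n_spots - len(accepted)), 256)
        idx = rng.integers(rows.size, size=m)
        jit = rng.uniform(0.0, 1.0, size=(m, 2))
        x = (cols[idx] + jit[:, 0]) * spec.pixel_size
        y = (rows[idx] + jit[:, 1]) * spec.pixel_size
        if spec.polarization_kappa > 0:
            theta = np.arctan2(y - cy, x - cx)
            acc_p = np.exp(
                spec.polarization_kappa * (np.cos(theta - spec.axis_angle) - 1.0)
            )
            keep = rng.uniform(size=m) < acc_p
        else:
            keep = np.ones(m, dtype=bool)
        for xi, yi in zip(x[keep], y[keep]):
            if len(accepted) < spec.n_spots:
                accepted.append(np.array([xi, yi]))
    return geometry, SpotSet(points=np.array(accepted))


@dataclasses.dataclass
class SyntheticImage:
    """Rendered smFISH image with its ground-truth spot list attached."""

    pixels: np.ndarray
    pixel_size: float
    truth: SpotSet


def render_smfish_image(
    geometry: CellGeometry,
    spots: SpotSet,
    psf_sigma: float = 0.2,
    amplitude: float = 200.0,
    background: float = 100.0,
    noise: str | tuple[str, float] | None = "poisson",
    seed: int = 0,
) -> SyntheticImage:
    """Render spots as isotropic Gaussians of SD ``psf_sigma`` (um) on a flat
    background, with Poisson or additive Gaussian noise.

    ``noise`` is ``"poisson"``, ``("gaussian", sd)`` or ``None``.
    """
    if psf_sigma <= 0:
        raise ValueError("psf_sigma must be positive")
    if amplitude < 0:
        raise ValueError("amplitude must be nonnegative")
    h, w = geometry.mask.shape
    px = geometry.pixel_size
    img = np.full((h, w), float(background))
    sigma_px = psf_sigma / px
    half = int(np.ceil(4 * sigma_px)) + 1
    for x_um, y_um in spots.points:
        c = x_um / px - 0.5
        r = y_um / px - 0.5
        if not (0 <= x_um < w * px and 0 <= y_um < h * px):
            raise ValueError(f"spot ({x_um:.2f}, {y_um:.2f}) um outside image bounds")
        r0, r1 = max(int(r) - half, 0), min(int(r) + half + 1, h)
        c0, c1 = max(int(c) - half, 0), min(int(c) + half + 1, w)
        rr, cc = np.mgrid[r0:r1, c0:c1]
        img[r0:r1, c0:c1] += amplitude * np.exp(
            -((rr - r) ** 2 + (cc - c) ** 2) / (2 * sigma_px**2)
        )
    rng = np.random.default_rng(seed)
    if noise == "poisson":
        img = rng.poisson(np.clip(img, 0, None)).astype(float)
    elif isinstance(noise, tuple) and noise[0] == "gaussian":
        img = img + rng.normal(0.0, float(noise[1]), size=img.shape)
    elif noise is not None:
        raise ValueError(f"unknown noise model {noise!r}")
    return SyntheticImage(pixels=img, pixel_size=px, truth=spots)


# ------------------------------------------------------------------ timelapse


@dataclasses.dataclass
class SimTimelapseSpec:
    """Reporter-particle tracks plus filopodia events in a cell ROI.

    Filopodium birth positions are drawn, with probability
    ``coupling_strength``, from an exponential kernel exp(-d / lambda)
    around a random particle at the emergence frame, otherwise uniformly in
    the ROI. Durations follow ``duration_base +
    duration_proximity_gain / (1 + d) + noise`` frames, where d is the true
    nearest-particle distance at emergence: a saturating gain reproducing a
    negative distance-duration trend without unbounded lifetimes. Events
    that would outlive the movie are truncated and flagged incomplete.
    """

    n_frames: int = 300
    frame_interval: float = 5.0  # seconds
    n_particles: int = 5
    particle_step_sd: float = 0.3  # um per frame
    n_filopodia: int = 99
    coupling_lambda: float = 2.0  # um
    coupling_strength: float = 0.0
    duration_base: float = 10.0  # frames
    duration_proximity_gain: float = 20.0  # frames at d = 0, saturating as 1/(1+d)
    duration_noise_sd: float = 2.0  # frames
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_frames, self.n_particles, self.n_filopodia) < 0:
            raise ValueError("counts must be nonnegative")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if not (0 <= self.coupling_strength <= 1):
            raise ValueError("coupling_strength must be in [0, 1]")
        if self.coupling_lambda <= 0:
            raise ValueError("coupling_lambda must be positive")


def disk_roi(radius_um: float = 30.0, pixel_size: float = 0.5) -> RoiStack:
    """A disk-shaped static ROI, a reasonable stand-in for a cell footprint."""
    mask = _ellipse_mask((radius_um, radius_um), pixel_size)
    return RoiStack(masks=mask, pixel_size=pixel_size)


def _uniform_in_mask(
    mask: np.ndarray, pixel_size: float, rng: np.random.Generator, n: int = 1
) -> np.ndarray:
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("empty ROI")
    idx = rng.integers(rows.size, size=n)
    jit = rng.uniform(0.0, 1.0, size=(n, 2))
    return np.column_stack(
        [(cols[idx] + jit[:, 0]) * pixel_size, (rows[idx] + jit[:, 1]) * pixel_size]
    )


def _inside(mask: np.ndarray, pixel_size: float, pt: np.ndarray) -> bool:
    c = int(np.floor(pt[0] / pixel_size))
    r = int(np.floor(pt[1] / pixel_size))
    return 0 <= r < mask.shape[0] and 0 <= c < mask.shape[1] and bool(mask[r, c])


def gen_timelapse(
    spec: SimTimelapseSpec, roi: RoiStack | None = None
) -> tuple[list[ParticleTrack], list[FilopodiumEvent], RoiStack]:
    """Simulate particle tracks and filopodia events inside an ROI.

    Particles start uniformly in the ROI and perform random walks confined
    to it (a step landing outside is redrawn, keeping the particle inside).
    Returns ``(tracks, events, roi)``.
    """
    if roi is None:
        roi = disk_roi()
    rng = np.random.default_rng(spec.seed)
    mask = roi.at(0)
    px = roi.pixel_size

    tracks: list[ParticleTrack] = []
    positions = _uniform_in_mask(mask, px, rng, spec.n_particles)
    frames = np.arange(spec.n_frames)
    history = np.zeros((spec.n_particles, spec.n_frames, 2))
    for t in range(spec.n_frames):
        m = roi.at(t)
        for i in range(spec.n_particles):
            if t == 0:
                history[i, 0] = positions[i]
                continue
            pt = history[i, t - 1]
            for _ in range(20):
                cand = pt + rng.normal(0.0, spec.particle_step_sd, size=2)
                if _inside(m, px, cand):
                    pt = cand
                    break
            history[i, t] = pt
    for i in range(spec.n_particles):
        tracks.append(ParticleTrack(track_id=f"track{i:03d}", frames=frames, xy=history[i]))

    from .proximity import nearest_particle_distance

    events: list[FilopodiumEvent] = []
    for j in range(spec.n_filopodia):
        t0 = int(rng.integers(1, max(spec.n_frames - 1, 2)))
        m = roi.at(t0)
        if spec.coupling_strength > 0 and rng.uniform() < spec.coupling_strength and spec.n_particles > 0:
            anchor = history[rng.integers(spec.n_particles), t0]
            base = None
            for _ in range(200):
                d = rng.exponential(spec.coupling_lambda)
                ang = rng.uniform(0, 2 * np.pi)
                cand = anchor + d * np.array([np.cos(ang), np.sin(ang)])
                if _inside(m, px, cand):
                    base = cand
                    break
            if base is None:
                base = _uniform_in_mask(m, px, rng, 1)[0]
        else:
            base = _uniform_in_mask(m, px, rng, 1)[0]
        if spec.n_particles > 0:
            d_true = nearest_particle_distance(base, tracks, t0)
        else:
            d_true = np.inf
        duration = (
            spec.duration_base
            + spec.duration_proximity_gain / (1.0 + d_true)
            + rng.normal(0.0, spec.duration_noise_sd)
        )
        duration = max(int(round(duration)), 1)
        t1 = t0 + duration
        complete = True
        if t1 > spec.n_frames - 1:
            t1 = spec.n_frames - 1
            complete = False
        events.append(
            FilopodiumEvent(
                event_id=f"filo{j:03d}",
                base=(float(base[0]), float(base[1])),
                t_emerge=t0,
                t_retract=t1,
                complete=complete,
            )
        )
    return tracks, events, roi


# ------------------------------------------------------------------ sequences


@dataclasses.dataclass
class SimSequenceSpec:
    """Background 3'UTR-like sequences with planted motif occurrences.

    ``copies_per_sequence`` is either one count applied to every sequence or
    a per-sequence list. Planted copies are the PWM consensus by default
    (``sample_from_pwm`` draws letters from the PWM instead) and are placed
    at non-overlapping random offsets.
    """

    planted_pwm: PWM
    n_sequences: int = 10
    length_range: tuple[int, int] = (200, 400)
    background_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    copies_per_sequence: Sequence[int] | int = 2
    sample_from_pwm: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sequences < 0:
            raise ValueError("n_sequences must be nonnegative")
        if abs(sum(self.background_freqs) - 1) > 1e-9:
            raise ValueError("background_freqs must sum to 1")
        if self.length_range[0] > self.length_range[1] or self.length_range[0] < 1:
            raise ValueError("invalid length_range")
        if isinstance(self.copies_per_sequence, int):
            self.copies_per_sequence = [self.copies_per_sequence] * self.n_sequences
        if len(self.copies_per_sequence) != self.n_sequences:
            raise ValueError("copies_per_sequence must match n_sequences")
        if any(c < 0 for c in self.copies_per_sequence):
            raise ValueError("copy counts must be nonnegative")


def _place_nonoverlapping(
    n_copies: int, length: int, width: int, rng: np.random.Generator
) -> list[int]:
    if n_copies * width > length:
        raise ValueError(
            f"{n_copies} copies of width {width} do not fit in {length} nt"
        )
    starts: list[int] = []
    for _ in range(10000):
        s = int(rng.integers(0, length - width + 1))
        if all(s + width <= t or s >= t + width for t in starts):
            starts.append(s)
            if len(starts) == n_copies:
                return sorted(starts)
    raise ValueError("could not place non-overlapping motif copies")


def gen_utr_sequences(spec: SimSequenceSpec):
    """Generate i.i.d.-background sequences with planted motif copies.

    Returns ``(sequences, truth)`` where ``sequences`` maps sequence id to
    string and ``truth`` is a DataFrame of planted (sequence_id, start,
    end) intervals, 0-based half-open.
    """
    import pandas as pd

    rng = np.random.default_rng(spec.seed)
    w = spec.planted_pwm.width
    letters = np.array(list(ALPHABET))
    sequences: dict[str, str] = {}
    rows = []
    for i in range(spec.n_sequences):
        sid = f"utr{i:04d}"
        length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        seq = rng.choice(letters, size=length, p=np.asarray(spec.background_freqs))
        n_copies = spec.copies_per_sequence[i]
        if n_copies > 0:
            starts = _place_nonoverlapping(n_copies, length, w, rng)
            for s in starts:
                if spec.sample_from_pwm:
                    planted = [
                        letters[rng.choice(4, p=spec.planted_pwm.probs[:, j])]
                        for j in range(w)
                    ]
                else:
                    planted = list(spec.planted_pwm.consensus)
                seq[s : s + w] = planted
                rows.append({"sequence_id": sid, "start": s, "end": s + w})
        sequences[sid] = "".join(seq)
    truth = pd.DataFrame(rows, columns=["sequence_id", "start", "end"])
    return sequences, truth
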