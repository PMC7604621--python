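"""Readers and writers for the pipeline's file formats, plus run configuration.

Formats: TSV fold-change/cluster tables (pandas), FASTA (Biopython), MEME
minimal motif format, TIFF images and mask stacks (tifffile), CSV spot /
track / filopodium-event tables, BED6-like motif hit tables. All sequence
intervals are 0-based half-open internally and on disk; figure-style 1-based
inclusive coordinates appear only in human-readable reports.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .motifs import PWM, MotifHit
from .proximity import FilopodiumEvent, ParticleTrack, RoiStack
from .spots import SpotSet

__all__ = [
    "RunConfig",
    "read_foldchange_table",
    "write_foldchange_table",
    "read_fasta",
    "write_fasta",
    "read_meme_motif",
    "write_meme_motif",
    "read_image",
    "write_image",
    "read_mask_stack",
    "write_mask_stack",
    "read_spot_table",
    "write_spot_table",
    "read_track_table",
    "write_track_table",
    "read_event_table",
    "write_event_table",
    "write_hits_bed",
    "read_hits_bed",
    "interval_length",
    "figure_region_to_interval",
]

logger = logging.getLogger(__name__)


# ------------------------------------------------------------------ intervals


def interval_length(interval: tuple[int, int]) -> int:
    """Length of a 0-based half-open interval [start, end)."""
    start, end = interval
    if end < start:
        raise ValueError("interval end must be >= start")
    return end - start


def figure_region_to_interval(start: int, end: int) -> tuple[int, int]:
    """Interpret a figure-style region like "90-282" as 0-based half-open.

    The convention here is that such regions already name half-open offsets,
    so region 90-282 denotes the 192-nt element [90, 282).
    """
    return (start, end)


# ----------------------------------------------------------------- TSV tables


def write_foldchange_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_foldchange_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns:
        raise ValueError(f"{path}: missing gene_id column")
    return df


# --------------------------------------------------------------------- FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into id -> uppercase sequence (U accepted alongside T)."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=sid, description="") for sid, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# --------------------------------------------------------------- MEME format

_MEME_HEADER = """MEME version 4

ALPHABET= ACGT

strands: +

Background letter frequencies
A {bg[0]:.6f} C {bg[1]:.6f} G {bg[2]:.6f} T {bg[3]:.6f}

MOTIF {name}
letter-probability matrix: alength= 4 w= {w} nsites= {nsites} E= 0
"""


def write_meme_motif(pwm: PWM, path: str | Path, nsites: int = 20) -> None:
    """Write a PWM in MEME minimal motif format."""
    lines = _MEME_HEADER.format(bg=pwm.background, name=pwm.name, w=pwm.width, nsites=nsites)
    body = "\n".join(
        " ".join(f"{pwm.probs[a, j]:.6f}" for a in range(4)) for j in range(pwm.width)
    )
    Path(path).write_text(lines + body + "\n")


def read_meme_motif(path: str | Path, which: int = 0) -> PWM:
    """Parse a MEME minimal motif file into a PWM.

    Columns whose probabilities sum to within 1e-3 of 1 are renormalised
    with a warning; a larger deviation is an error naming the line.
    """
    text = Path(path).read_text().splitlines()
    background = np.full(4, 0.25)
    motifs: list[tuple[str, list[list[float]], int]] = []
    i = 0
    while i < len(text):
        line = text[i].strip()
        if line.startswith("Background letter frequencies"):
            vals = text[i + 1].split()
            background = np.array([float(vals[k]) for k in (1, 3, 5, 7)])
            i += 2
            continue
        if line.startswith("MOTIF"):
            name = line.split()[1] if len(line.split()) > 1 else "motif"
            j = i + 1
            while j < len(text) and not text[j].strip().startswith("letter-probability"):
                j += 1
            if j == len(text):
                raise ValueError(f"{path}:{i + 1}: MOTIF without probability matrix")
            header = text[j]
            w = int(header.split("w=")[1].split()[0])
            rows = []
            for k in range(w):
                parts = text[j + 1 + k].split()
                if len(parts) < 4:
                    raise ValueError(f"{path}:{j + 2 + k}: malformed matrix row")
                rows.append([float(v) for v in parts[:4]])
            motifs.append((name, rows, j))
            i = j + 1 + w
            continue
        i += 1
    if not motifs:
        raise ValueError(f"{path}: no MOTIF records found")
    name, rows, line_no = motifs[which]
    probs = np.array(rows).T  # (4, w)
    sums = probs.sum(axis=0)
    off = np.abs(sums - 1)
    if np.any(off > 1e-3 + 1e-9):
        bad = int(np.argmax(off))
        raise ValueError(
            f"{path}:{line_no + 2 + bad}: column probabilities sum to {sums[bad]:.4f}"
        )
    if np.any(off > 1e-4):
        warnings.warn(f"{path}: renormalising motif columns (max deviation {off.max():.2g})")
    probs = probs / sums
    return PWM(probs=probs, background=background, name=name)


# -------------------------------------------------------------------- images


def write_image(image: np.ndarray, path: str | Path) -> None:
    """Write a 2D image as 16-bit grayscale TIFF (values clipped)."""
    arr = np.clip(np.asarray(image), 0, 65535).astype(np.uint16)
    tifffile.imwrite(str(path), arr)


def read_image(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(float)


def write_mask_stack(roi: RoiStack, path: str | Path) -> None:
    """Write per-frame ROI masks as a multi-page 8-bit TIFF."""
    tifffile.imwrite(str(path), roi.masks.astype(np.uint8) * 255)


def read_mask_stack(path: str | Path, pixel_size: float) -> RoiStack:
    arr = tifffile.imread(str(path))
    return RoiStack(masks=arr > 0, pixel_size=pixel_size)


# --------------------------------------------------------------- CSV tables


def write_spot_table(spots: SpotSet, path: str | Path) -> None:
    pd.DataFrame(
        {
            "cell_id": spots.cell_id,
            "x_um": spots.points[:, 0],
            "y_um": spots.points[:, 1],
            "intensity": spots.intensity,
        }
    ).to_csv(path, index=False, float_format="%.6g")


def read_spot_table(path: str | Path) -> dict[str, SpotSet]:
    df = pd.read_csv(path)
    out = {}
    for cell_id, grp in df.groupby("cell_id"):
        out[str(cell_id)] = SpotSet(
            points=grp[["x_um", "y_um"]].to_numpy(),
            intensity=grp["intensity"].to_numpy(),
            cell_id=str(cell_id),
        )
    return out


def write_track_table(tracks: list[ParticleTrack], path: str | Path) -> None:
    frames = []
    for t in tracks:
        frames.append(
            pd.DataFrame(
                {
                    "track_id": t.track_id,
                    "frame": t.frames,
                    "x_um": t.xy[:, 0],
                    "y_um": t.xy[:, 1],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.6g")


def read_track_table(path: str | Path) -> list[ParticleTrack]:
    df = pd.read_csv(path)
    tracks = []
    for tid, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("frame")
        tracks.append(
            ParticleTrack(
                track_id=str(tid),
                frames=grp["frame"].to_numpy(dtype=int),
                xy=grp[["x_um", "y_um"]].to_numpy(),
            )
        )
    return tracks


def write_event_table(events: list[FilopodiumEvent], path: str | Path) -> None:
    pd.DataFrame(
        {
            "event_id": [e.event_id for e in events],
            "x_um": [e.base[0] for e in events],
            "y_um": [e.base[1] for e in events],
            "t_emerge": [e.t_emerge for e in events],
            "t_retract": [e.t_retract for e in events],
            "complete": [e.complete for e in events],
        }
    ).to_csv(path, index=False, float_format="%.6g")


def read_event_table(path: str | Path) -> list[FilopodiumEvent]:
    df = pd.read_csv(path)
    return [
        FilopodiumEvent(
            event_id=str(r.event_id),
            base=(float(r.x_um), float(r.y_um)),
            t_emerge=int(r.t_emerge),
            t_retract=int(r.t_retract),
            complete=bool(r.complete),
        )
        for r in df.itertuples()
    ]


# ------------------------------------------------------------------ hit BED


def write_hits_bed(hits: list[MotifHit], path: str | Path, name: str = "motif") -> None:
    """Write motif hits as BED6-like TSV with an extra p_value column."""
    pd.DataFrame(
        {
            "sequence_id": [h.sequence_id for h in hits],
            "start": [h.start for h in hits],
            "end": [h.end for h in hits],
            "name": name,
            "score": [h.score for h in hits],
            "strand": "+",
            "p_value": [h.p_value for h in hits],
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_hits_bed(path: str | Path) -> list[MotifHit]:
    df = pd.read_csv(path, sep="\t")
    return [
        MotifHit(
            sequence_id=str(r.sequence_id),
            start=int(r.start),
            end=int(r.end),
            score=float(r.score),
            p_value=float(r.p_value),
        )
        for r in df.itertuples()
    ]


# --------------------------------------------------------------- run config


@dataclasses.dataclass
class RunConfig:
    """Parameters for a full synthetic pipeline run.

    Thresholds default to the standard analysis settings: enrichment FC > 1.6 and
    FC < 0.625 at q < 0.05, k = 8 status clusters, motif match p < 1e-5
    with the >= 2-occurrence statistic, 5-um proximity bins and 12-um
    distal-axis bins.
    """

    seed: int = 0
    fc_hi: float = 1.6
    fc_lo: float = 0.625
    q_max: float = 0.05
    k: int = 8
    n_starts: int = 20
    p_max: float = 1e-5
    min_count: int = 2
    bin_width_um: float = 5.0
    axial_bin_um: float = 12.0
    # synthetic-stage sizes
    n_genes_per_status: int = 50
    foldchange_noise_sd: float = 0.2
    frac_null_pvalues: float = 0.2
    # a width-8 motif on uniform background has best p-value 4**-8 > 1e-5,
    # so planted motifs must be >= 9 nt to be recoverable at p_max = 1e-5
    motif_width: int = 10
    utr_copies_universal: int = 3
    utr_copies_other: int = 0
    n_cells: int = 20
    spots_per_cell: int = 150
    polarization_kappa: float = 5.0
    n_filopodia: int = 99
    coupling_strength: float = 1.0
    coupling_lambda: float = 2.0
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ValueError(f"unknown configuration key(s): {unknown}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: configuration must be a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))
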