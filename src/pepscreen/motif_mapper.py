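"""Minimal-motif inference from runs of extreme overlapping windows.

When consecutive k-mer windows of a tiled protein are all extreme (e.g. all
cell-repellent), the residues shared by every window in the run — the
intersection of r consecutive k-mers, of length k − r + 1 — are the minimal
candidate motif, mapped back onto 1-based protein coordinates. This is how
a 3-residue repellent motif such as EVK emerges from a run of 13 flagged
15-mer windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .library_design import PeptideEntry, ProteinRecord


@dataclass
class WindowTrack:
    """Per-start Int. values for one tiled protein (index 0 = start 1)."""

    protein_id: str
    k: int
    values: np.ndarray  # length L - k + 1; NaN where the window is unmeasured
    flags: np.ndarray | None = None  # True where the window is extreme

    def __len__(self) -> int:
        return len(self.values)

    def value_at(self, start: int) -> float:
        """Int. of the window with 1-based start position *start*."""
        return float(self.values[start - 1])

    def set_flags(self, threshold: float, side: str = "repulsive") -> None:
        """Flag extreme windows: Int. <= threshold (repulsive) or >= (adhesive).

        Unmeasured (NaN) windows are never flagged.
        """
        if side not in ("repulsive", "adhesive"):
            raise ValueError("side must be 'repulsive' or 'adhesive'")
        with np.errstate(invalid="ignore"):
            if side == "repulsive":
                flags = self.values <= threshold
            else:
                flags = self.values >= threshold
        flags[np.isnan(self.values)] = False
        self.flags = flags


def window_track(
    protein: ProteinRecord,
    measurements: Mapping[str, float],
    library: Sequence[PeptideEntry],
    k: int = 15,
) -> WindowTrack:
    """Place each scan window's Int. at its start position; gaps stay NaN."""
    n = protein.length - k + 1
    if n < 1:
        raise ValueError(f"protein {protein.id!r} is shorter than k={k}")
    windows = [
        e
        for e in library
        if e.group == "scan" and e.source_protein == protein.id
    ]
    if not windows:
        raise ValueError(f"library contains no scan windows for protein {protein.id!r}")
    values = np.full(n, np.nan)
    for e in windows:
        if e.start is None or not (1 <= e.start <= n):
            raise ValueError(f"scan window {e.peptide_id!r} start {e.start} out of range")
        if e.sequence != protein.sequence[e.start - 1 : e.start - 1 + k]:
            raise ValueError(
                f"scan window {e.peptide_id!r} does not match protein {protein.id!r} "
                f"at start {e.start}"
            )
        if e.peptide_id in measurements:
            values[e.start - 1] = float(measurements[e.peptide_id])
    return WindowTrack(protein_id=protein.id, k=k, values=values)


@dataclass(frozen=True)
class MotifCall:
    protein_id: str
    motif: str  # "" when the run is longer than k (no shared core)
    start: int  # 1-based inclusive residue coordinates of the motif
    end: int
    run_length: int
    mean_intensity: float
    empty_core: bool = False


def infer_minimal_motifs(track: WindowTrack, protein: ProteinRecord) -> list[MotifCall]:
    """One motif call per maximal run of consecutive flagged windows.

    A run of r flagged windows starting at window start i shares exactly the
    residues [i + r − 1, i + k − 1] (length k − r + 1). Runs longer than k
    have no shared residue; they are reported with an empty motif, the run's
    residue span, and ``empty_core=True`` instead of being dropped. Calls
    are sorted by mean Int. over the run (most extreme first for repulsive
    tracks).
    """
    if track.flags is None:
        raise ValueError("track flags are unset; call set_flags() first")
    k = track.k
    calls: list[MotifCall] = []
    flags = track.flags
    i = 0
    while i < len(flags):
        if not flags[i]:
            i += 1
            continue
        j = i
        while j + 1 < len(flags) and flags[j + 1]:
            j += 1
        r = j - i + 1
        run_mean = float(np.nanmean(track.values[i : j + 1]))
        start_w = i + 1  # 1-based start of the first window in the run
        if r <= k:
            start = start_w + r - 1
            end = start_w + k - 1
            motif = protein.sequence[start - 1 : end]
            calls.append(
                MotifCall(
                    protein_id=track.protein_id,
                    motif=motif,
                    start=start,
                    end=end,
                    run_length=r,
                    mean_intensity=run_mean,
                )
            )
        else:
            calls.append(
                MotifCall(
                    protein_id=track.protein_id,
                    motif="",
                    start=start_w,
                    end=start_w + k + r - 2,
                    run_length=r,
                    mean_intensity=run_mean,
                    empty_core=True,
                )
            )
        i = j + 1
    calls.sort(key=lambda c: (c.mean_intensity, c.start))
    return calls


def export_residue_track(
    calls: Sequence[MotifCall],
    protein: ProteinRecord,
    bed_path: str | Path,
    tsv_path: str | Path,
    header_comment: str | None = None,
) -> None:
    """Write motif calls as a BED file (0-based half-open) and a per-residue TSV.

    BED score is the run's mean Int. scaled into [0, 1000] over the calls.
    """
    for c in calls:
        if not (1 <= c.start <= c.end <= protein.length):
            raise ValueError(
                f"motif call [{c.start}, {c.end}] outside protein {protein.id!r} bounds"
            )
    intensities = [c.mean_intensity for c in calls]
    lo = min(intensities) if intensities else 0.0
    hi = max(intensities) if intensities else 1.0
    span = hi - lo if hi > lo else 1.0
    with open(bed_path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write(f'track name="pepscreen_motifs_{protein.id}"\n')
        for c in calls:
            score = int(round(1000 * (c.mean_intensity - lo) / span))
            name = c.motif if c.motif else f"empty_core_run{c.run_length}"
            fh.write(f"{protein.id}\t{c.start - 1}\t{c.end}\t{name}\t{score}\t.\n")
    in_motif = np.zeros(protein.length, dtype=bool)
    for c in calls:
        if c.motif:
            in_motif[c.start - 1 : c.end] = True
    with open(tsv_path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("protein\tposition\tresidue\tin_motif\n")
        for pos0, aa in enumerate(protein.sequence):
            fh.write(f"{protein.id}\t{pos0 + 1}\t{aa}\t{int(in_motif[pos0])}\n")
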