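"""Replicate aggregation, the ranked intensity curve, extreme-peptide
detection, and peptide property sums.

Per peptide, the screen's intensity *Int.* is the median over its replicate
spots. Sorting all peptides by *Int.* gives a curve whose body rises
gradually while specifically repulsive and adhesive peptides separate from
it through sharp jumps (gradient spikes) at the edges. Peptide properties
(total charge, total MW, summed hydrophobicity SH, summed helix propensity
HP) are per-residue table sums used to probe sequence-level trends.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .constants import BLANK_ID, WATER_MW, validate_sequence
from .quantification import SpotQuantification


@dataclass(frozen=True)
class PeptideMeasurement:
    peptide_id: str
    replicate_intensities: tuple[float, ...]
    intensity: float  # Int.: median of the replicate spot intensities

    @classmethod
    def from_replicates(cls, peptide_id: str, values: Sequence[float]) -> "PeptideMeasurement":
        if len(values) == 0:
            raise ValueError(f"peptide {peptide_id!r} has no replicate intensities")
        return cls(
            peptide_id=peptide_id,
            replicate_intensities=tuple(float(v) for v in values),
            intensity=float(np.median(values)),
        )


def aggregate_replicates(
    quantifications: Iterable[SpotQuantification],
    blank_ids: frozenset[str] | None = None,
) -> tuple[list[PeptideMeasurement], list[str]]:
    """One measurement per peptide: Int. = median of its replicate spots.

    All blank spots (the literal "BLANK" filler plus any ids in *blank_ids*)
    are pooled under the single id "BLANK". Returns the measurements and the
    ids of peptides excluded for having zero spots (always empty here, kept
    for reporting symmetry with partial quantifications).
    """
    blanks = blank_ids or frozenset()
    grouped: dict[str, list[float]] = {}
    for q in quantifications:
        pid = BLANK_ID if (q.peptide_id == BLANK_ID or q.peptide_id in blanks) else q.peptide_id
        grouped.setdefault(pid, []).append(q.median_intensity)
    measurements = [
        PeptideMeasurement.from_replicates(pid, values) for pid, values in grouped.items()
    ]
    measurements.sort(key=lambda m: m.peptide_id)
    return measurements, []


def intensity_map(measurements: Iterable[PeptideMeasurement]) -> dict[str, float]:
    return {m.peptide_id: m.intensity for m in measurements}


@dataclass
class RankedCurve:
    """Measurements in ascending Int. order plus the discrete gradient."""

    peptide_ids: list[str]
    intensities: np.ndarray
    gradient: np.ndarray  # gradient[i] = intensities[i+1] - intensities[i]

    def __len__(self) -> int:
        return len(self.peptide_ids)


def rank_curve(measurements: Sequence[PeptideMeasurement]) -> RankedCurve:
    """Ascending sort by Int. (ties broken by peptide_id) with its gradient."""
    if len(measurements) < 2:
        raise ValueError("rank curve needs at least 2 measurements")
    ordered = sorted(measurements, key=lambda m: (m.intensity, m.peptide_id))
    intensities = np.array([m.intensity for m in ordered])
    return RankedCurve(
        peptide_ids=[m.peptide_id for m in ordered],
        intensities=intensities,
        gradient=np.diff(intensities),
    )


@dataclass(frozen=True)
class ExtremeCall:
    peptide_id: str
    side: str  # "repulsive" | "adhesive"
    rank: int  # 1-based position on the ascending curve
    intensity: float


def detect_extremes(
    ranked: RankedCurve,
    q_low: float = 0.05,
    q_high: float = 0.95,
    gradient_factor: float = 3.0,
    fallback: str = "none",
    method: str = "gradient",
) -> tuple[list[ExtremeCall], dict]:
    """Call repulsive/adhesive peptides from gradient spikes at the curve edges.

    A spike is a gradient exceeding ``gradient_factor`` times the median
    gradient of the whole curve. Scanning in ascending rank order, the first
    spike inside the low-edge window ends the repulsive region, and the
    first spike inside the high-edge window starts the adhesive region. When
    a window has no spike, the behaviour is governed by *fallback*: "none"
    emits no calls for that side, "quantile" cuts at the plain quantile.
    ``method="quantile"`` bypasses the gradient rule and cuts both edges at
    their quantile windows (rank-only, hence invariant to monotone
    transforms of the intensities).

    Returns the calls and a report of the parameters, boundaries and
    whether the fallback fired.
    """
    if not (0 < q_low < q_high < 1):
        raise ValueError("quantiles must satisfy 0 < q_low < q_high < 1")
    if fallback not in ("none", "quantile"):
        raise ValueError("fallback must be 'none' or 'quantile'")
    if method not in ("gradient", "quantile"):
        raise ValueError("method must be 'gradient' or 'quantile'")
    n = len(ranked)
    w_low = int(np.floor(q_low * n))
    w_high = n - int(np.ceil(q_high * n))
    if w_low < 1 or w_high < 1:
        raise ValueError(
            f"curve of {n} peptides is shorter than the edge windows "
            f"(q_low={q_low}, q_high={q_high})"
        )
    g = ranked.gradient
    threshold = gradient_factor * float(np.median(g))
    report: dict = {
        "n": n,
        "q_low": q_low,
        "q_high": q_high,
        "gradient_factor": gradient_factor,
        "gradient_threshold": threshold,
        "fallback": fallback,
        "method": method,
        "boundary_low": None,
        "boundary_high": None,
        "fallback_used_low": False,
        "fallback_used_high": False,
    }
    calls: list[ExtremeCall] = []

    low_spikes = np.flatnonzero(g[:w_low] > threshold) if method == "gradient" else []
    if method == "quantile":
        boundary_low = w_low
    elif len(low_spikes):
        boundary_low = int(low_spikes[0]) + 1  # ranks 1..boundary_low are repulsive
    elif fallback == "quantile":
        boundary_low = w_low
        report["fallback_used_low"] = True
    else:
        boundary_low = 0
    report["boundary_low"] = boundary_low
    for i in range(boundary_low):
        calls.append(
            ExtremeCall(
                peptide_id=ranked.peptide_ids[i],
                side="repulsive",
                rank=i + 1,
                intensity=float(ranked.intensities[i]),
            )
        )

    high_start = n - 1 - w_high  # gradient indices [high_start, n-2] span the window
    high_spikes = np.flatnonzero(g[high_start:] > threshold) if method == "gradient" else []
    if method == "quantile":
        first_adhesive = n - w_high
    elif len(high_spikes):
        boundary_high = high_start + int(high_spikes[0])  # first rank above = boundary_high+1
        first_adhesive = boundary_high + 1
    elif fallback == "quantile":
        first_adhesive = n - w_high
        report["fallback_used_high"] = True
    else:
        first_adhesive = n
    report["boundary_high"] = first_adhesive
    for i in range(first_adhesive, n):
        calls.append(
            ExtremeCall(
                peptide_id=ranked.peptide_ids[i],
                side="adhesive",
                rank=i + 1,
                intensity=float(ranked.intensities[i]),
            )
        )
    return calls, report


def blank_floor_threshold(blank_values: Sequence[float], n_mads: float = 2.0) -> float:
    """Repulsion threshold from the empty-spot signal: median + n_mads * MAD."""
    if len(blank_values) == 0:
        raise ValueError("no blank values supplied")
    med = float(np.median(blank_values))
    mad = float(stats.median_abs_deviation(blank_values, scale=1.0))
    return med + n_mads * mad


# ---------------------------------------------------------------------------
# Peptide property sums
# ---------------------------------------------------------------------------

_SCALE_FILES = {
    "kyte_doolittle": "kyte_doolittle.json",
    "pace_scholtz": "pace_scholtz.json",
    "charge_default": "charge_default.json",
    "residue_mass_average": "residue_mass_average.json",
}


def load_scale(name: str) -> dict[str, float]:
    """Load a named per-residue table shipped with the package."""
    try:
        fname = _SCALE_FILES[name]
    except KeyError:
        raise KeyError(f"unknown scale {name!r}; available: {sorted(_SCALE_FILES)}") from None
    text = resources.files("pepscreen.data").joinpath(fname).read_text()
    return {aa: float(v) for aa, v in json.loads(text)["values"].items()}


@dataclass
class PropertyScales:
    """The four per-residue tables behind the property sums (swappable by name)."""

    charge: str = "charge_default"
    mw: str = "residue_mass_average"
    hydrophobicity: str = "kyte_doolittle"
    helix: str = "pace_scholtz"

    def tables(self) -> dict[str, dict[str, float]]:
        return {
            "charge": load_scale(self.charge),
            "mw": load_scale(self.mw),
            "hydrophobicity": load_scale(self.hydrophobicity),
            "helix": load_scale(self.helix),
        }


@dataclass(frozen=True)
class PropertyProfile:
    peptide_id: str
    total_charge: float
    total_mw: float  # residue masses + one water per (non-empty) peptide, Da
    sh: float  # summed hydrophobicity
    hp: float  # summed helix propensity


def compute_property_profile(
    sequence: str, scales: PropertyScales | None = None, peptide_id: str | None = None
) -> PropertyProfile:
    """Per-residue table sums for one peptide; the empty sequence is all zeros."""
    scales = scales or PropertyScales()
    validate_sequence(sequence, allow_empty=True, context="peptide")
    tables = scales.tables()
    pid = peptide_id if peptide_id is not None else sequence
    if not sequence:
        return PropertyProfile(pid, 0.0, 0.0, 0.0, 0.0)
    return PropertyProfile(
        peptide_id=pid,
        total_charge=sum(tables["charge"][aa] for aa in sequence),
        total_mw=sum(tables["mw"][aa] for aa in sequence) + WATER_MW,
        sh=sum(tables["hydrophobicity"][aa] for aa in sequence),
        hp=sum(tables["helix"][aa] for aa in sequence),
    )


PROPERTY_NAMES = ("total_charge", "total_mw", "sh", "hp")


def correlate_properties(
    measurements: Sequence[PeptideMeasurement],
    profiles: Sequence[PropertyProfile],
    n_permutations: int = 999,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman rank correlation of Int. against each property sum.

    Two-sided p-values come from a seeded permutation test (no multiplicity
    correction across the four properties). Returns (correlation report,
    tidy scatter table for plotting).
    """
    prof_by_id = {p.peptide_id: p for p in profiles}
    pairs = [(m, prof_by_id[m.peptide_id]) for m in measurements if m.peptide_id in prof_by_id]
    if len(pairs) < 3:
        raise ValueError(f"need >= 3 matched peptide/profile pairs, got {len(pairs)}")
    intensity = np.array([m.intensity for m, _ in pairs])
    rng = np.random.default_rng(seed)
    rows = []
    scatter_rows = []
    perm_idx = np.array([rng.permutation(len(pairs)) for _ in range(n_permutations)])
    intensity_ranks = stats.rankdata(intensity)
    for prop in PROPERTY_NAMES:
        values = np.array([getattr(p, prop) for _, p in pairs])
        if np.ptp(values) == 0 or np.ptp(intensity) == 0:
            # a constant input has no defined rank correlation
            rows.append(
                {"property": prop, "spearman_rho": float("nan"),
                 "p_permutation": float("nan"), "n": len(pairs)}
            )
            for (m, pr), v in zip(pairs, values):
                scatter_rows.append(
                    {"peptide_id": m.peptide_id, "property": prop,
                     "value": float(v), "intensity": m.intensity}
                )
            continue
        rho = float(stats.spearmanr(intensity, values).statistic)
        value_ranks = stats.rankdata(values)
        # permutation null: Pearson of the (fixed) rank vectors under shuffles
        null = np.array(
            [
                np.corrcoef(intensity_ranks, value_ranks[idx])[0, 1]
                for idx in perm_idx
            ]
        )
        p = float((1 + np.sum(np.abs(null) >= abs(rho) - 1e-12)) / (n_permutations + 1))
        rows.append({"property": prop, "spearman_rho": rho, "p_permutation": p, "n": len(pairs)})
        for (m, pr), v in zip(pairs, values):
            scatter_rows.append(
                {"peptide_id": m.peptide_id, "property": prop, "value": float(v), "intensity": m.intensity}
            )
    return pd.DataFrame(rows), pd.DataFrame(scatter_rows)


def measurements_to_frame(measurements: Iterable[PeptideMeasurement]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "peptide_id": [m.peptide_id for m in measurements],
            "n_replicates": [len(m.replicate_intensities) for m in measurements],
            "intensity": [m.intensity for m in measurements],
            "replicate_intensities": [
                ",".join(f"{v:.6g}" for v in m.replicate_intensities) for m in measurements
            ],
        }
    )
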