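"""Matching calculated shifts to experimental peaks.

For each candidate structure, the probability that calculated shift i
belongs to experimental peak j is tabulated in a matrix M; the most
probable global assignment maximises the product of matrix entries,
found as a minimum-cost matching on -log M by the Hungarian algorithm.

Systematic prediction error is handled in three stages: (1) a linear
rescale with known external scaling factors, then a first assignment;
(2) internal scaling factors regressed from that assignment, a rescale
and a second assignment; (3) for carbon only, a bias pass that rescues
intense unassigned peaks near each assigned shift.

Carbon peaks may be assigned more than once (degenerate carbons).  Each
extra use of peak j is discounted by the multiple-assignment penalty
``(1 / (1 + t)) ** k`` where t counts prior uses of the peak and k is
the peak's amplitude-group rank (1 = most intense group).  Entries are
also multiplied by the amplitude weight A_j from the carbon pipeline.
Proton assignment needs none of this -- integral normalisation says
exactly how many protons each multiplet may take -- but adds a methyl
stage: the three protons of each methyl group are assigned as one unit
to a multiplet with at least three protons of capacity.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .carbon import CarbonPeak
from .dp4 import ErrorModel, error_pdf
from .proton import Multiplet

__all__ = [
    "CandidateShifts",
    "AssignmentMatrix",
    "AtomAssignment",
    "AssignmentResult",
    "boltzmann_average",
    "scale_external",
    "scale_internal",
    "multiple_assignment_penalty",
    "build_matrix",
    "assign_hungarian",
    "bias_reassign",
    "assign_carbons",
    "assign_protons",
    "read_shift_table",
    "write_assignment_report",
]

logger = logging.getLogger(__name__)

_GAS_CONSTANT_KJ = 8.31446261815324e-3  # kJ / (mol K)
_PDF_FLOOR = 1e-300


@dataclass
class CandidateShifts:
    """Calculated shifts for one candidate isomer."""

    candidate_id: str
    nucleus: str
    atoms: list[tuple[str, float]]  # (label, shift ppm)
    methyl_groups: list[tuple[str, str, str]] = field(default_factory=list)
    labile_labels: frozenset[str] = frozenset()
    conformer_block: list[tuple[float, dict[str, float]]] | None = None

    def __post_init__(self) -> None:
        labels = [a for a, _ in self.atoms]
        if len(set(labels)) != len(labels):
            raise ValueError("atom labels must be unique")
        seen: set[str] = set()
        for trio in self.methyl_groups:
            if seen & set(trio):
                raise ValueError("methyl groups must be disjoint")
            seen |= set(trio)

    @property
    def labels(self) -> list[str]:
        return [a for a, _ in self.atoms]

    @property
    def values(self) -> np.ndarray:
        return np.array([v for _, v in self.atoms], dtype=float)


def boltzmann_average(
    conformer_block: list[tuple[float, dict[str, float]]],
    temperature: float = 298.15,
    shielding_reference: tuple[float, float] | None = None,
) -> dict[str, float]:
    """Boltzmann-weighted per-atom shifts over conformers.

    ``conformer_block`` holds (relative energy kJ/mol, per-atom value)
    pairs.  Weights are proportional to ``exp(-dE / RT)``.  When
    ``shielding_reference = (ref, slope)`` is given, values are treated
    as isotropic shieldings and mapped to shifts via
    ``(ref - value) / slope``.
    """
    if not conformer_block:
        raise ValueError("need at least one conformer")
    kept = [(e, v) for e, v in conformer_block if math.isfinite(e)]
    if len(kept) < len(conformer_block):
        warnings.warn("dropping conformers with non-finite energies", stacklevel=2)
    if not kept:
        raise ValueError("no conformer with a finite energy")
    energies = np.array([e for e, _ in kept])
    energies = energies - energies.min()
    w = np.exp(-energies / (_GAS_CONSTANT_KJ * temperature))
    w /= w.sum()
    labels = list(kept[0][1])
    out: dict[str, float] = {}
    for lab in labels:
        vals = np.array([v[lab] for _, v in kept])
        avg = float(np.sum(w * vals))
        if shielding_reference is not None:
            ref, slope = shielding_reference
            avg = (ref - avg) / slope
        out[lab] = avg
    return out


def scale_external(shifts: np.ndarray, factors: tuple[float, float]) -> np.ndarray:
    """Undo a known systematic linear distortion: (shift - intercept)/slope."""
    slope, intercept = factors
    if not (np.isfinite(slope) and np.isfinite(intercept)) or slope == 0:
        raise ValueError("scaling factors must be finite with nonzero slope")
    return (np.asarray(shifts, dtype=float) - intercept) / slope


def scale_internal(
    pairs: list[tuple[float, float]],
    slope_range: tuple[float, float] = (0.8, 1.2),
) -> tuple[float, float]:
    """Regress calculated on experimental shifts from an assignment.

    Ordinary least squares with one robustness pass: points whose
    residual exceeds three (scaled) median absolute deviations are
    dropped and the line refitted.  Returns identity (1, 0) with a
    warning for fewer than three pairs, degenerate spread, or a slope
    outside ``slope_range``.
    """
    if len(pairs) < 3:
        warnings.warn("fewer than 3 assigned pairs; internal scaling skipped", stacklevel=2)
        return 1.0, 0.0
    calc = np.array([c for c, _ in pairs])
    exp = np.array([e for _, e in pairs])
    if np.ptp(exp) < 1e-9:
        warnings.warn("degenerate experimental spread; internal scaling skipped", stacklevel=2)
        return 1.0, 0.0

    def ols(c: np.ndarray, e: np.ndarray) -> tuple[float, float]:
        slope, intercept = np.polyfit(e, c, 1)
        return float(slope), float(intercept)

    slope, intercept = ols(calc, exp)
    resid = calc - (slope * exp + intercept)
    mad = np.median(np.abs(resid - np.median(resid))) / 0.6745
    if mad > 0:
        keep = np.abs(resid - np.median(resid)) <= 3 * mad
        if keep.sum() >= 3 and keep.sum() < len(pairs):
            slope, intercept = ols(calc[keep], exp[keep])
    if not (slope_range[0] <= slope <= slope_range[1]):
        warnings.warn(
            f"internal slope {slope:.3f} outside {slope_range}; using identity",
            stacklevel=2,
        )
        return 1.0, 0.0
    return slope, intercept


def multiple_assignment_penalty(t: int, k: int) -> float:
    """Discount for assigning a peak its (t+1)-th time; k is group rank."""
    return (1.0 / (1.0 + t)) ** k


@dataclass
class AssignmentMatrix:
    """Probability matrix over (shift, peak-replication) pairs."""

    entries: np.ndarray  # (n_shifts, n_columns)
    shift_labels: list[str]
    column_peaks: list[int]  # peak index per column
    column_t: list[int]  # replication count per column

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.entries)) or np.any(self.entries < 0):
            raise ValueError("matrix entries must be finite and non-negative")


def build_matrix(
    scaled_shifts: np.ndarray,
    shift_labels: list[str],
    peak_positions: np.ndarray,
    error_model: ErrorModel,
    nucleus: str,
    peak_weights: np.ndarray | None = None,
    peak_groups: np.ndarray | None = None,
    replications: int = 1,
) -> AssignmentMatrix:
    """Tabulate P(shift i <-> peak j).

    Entries are the error-model density of ``scaled_shift_i - peak_j``.
    For carbon, each entry is multiplied by the peak's amplitude weight
    and, for replicated columns (t > 0), by the multiple-assignment
    penalty; proton matrices use neither.
    """
    scaled_shifts = np.asarray(scaled_shifts, dtype=float)
    peak_positions = np.asarray(peak_positions, dtype=float)
    base = error_pdf(
        scaled_shifts[:, None] - peak_positions[None, :], error_model
    )
    cols, col_peak, col_t = [], [], []
    for t in range(replications):
        for j in range(peak_positions.size):
            col = base[:, j]
            if nucleus == "C13":
                w = 1.0 if peak_weights is None else float(peak_weights[j])
                k = 1 if peak_groups is None else int(peak_groups[j])
                col = col * w * multiple_assignment_penalty(t, k)
            cols.append(col)
            col_peak.append(j)
            col_t.append(t)
    entries = np.stack(cols, axis=1)
    return AssignmentMatrix(entries, list(shift_labels), col_peak, col_t)


def assign_hungarian(matrix: AssignmentMatrix) -> list[tuple[int, int]]:
    """Most probable assignment: rows to columns, every shift matched.

    Maximising the product of probabilities is the minimum-cost matching
    on ``-log M``; all-zero rows are floored (and flagged) so the shift
    still lands on its best available column.
    """
    M = matrix.entries
    if M.shape[0] > M.shape[1]:
        raise ValueError(
            f"{M.shape[0]} shifts cannot be matched to {M.shape[1]} columns; "
            "replicate peak columns first"
        )
    zero_rows = np.flatnonzero(M.max(axis=1) <= 0)
    if zero_rows.size:
        warnings.warn(
            f"{zero_rows.size} shift(s) have zero probability everywhere; "
            "matching by floored cost",
            stacklevel=2,
        )
    cost = -np.log(np.clip(M, _PDF_FLOOR, None))
    rows, cols = linear_sum_assignment(cost)
    return sorted(zip(rows.tolist(), cols.tolist()))


@dataclass
class AtomAssignment:
    peak_index: int
    peak_ppm: float
    scaled_shift: float
    error: float  # scaled_shift - peak_ppm


@dataclass
class AssignmentResult:
    """Final atom-to-peak matching for one candidate and nucleus."""

    candidate_id: str
    nucleus: str
    atoms: dict[str, AtomAssignment]
    scaling_stages: list[tuple[str, float, float]] = field(default_factory=list)
    reassignment_log: list[str] = field(default_factory=list)
    unassigned_peaks: list[int] = field(default_factory=list)

    @property
    def errors(self) -> np.ndarray:
        return np.array([a.error for a in self.atoms.values()])

    def assigned_counts(self, n_peaks: int) -> np.ndarray:
        counts = np.zeros(n_peaks, dtype=int)
        for a in self.atoms.values():
            counts[a.peak_index] += 1
        return counts


def read_shift_table(
    path,
    candidate_id: str | None = None,
    nucleus: str = "C13",
    temperature: float = 298.15,
    shielding_reference: tuple[float, float] | None = None,
    methyl_groups: list[tuple[str, str, str]] | None = None,
    labile_labels: frozenset[str] = frozenset(),
) -> CandidateShifts:
    """Read a delimited calculated-shift table into CandidateShifts.

    Expected columns: ``atom_label, shift_ppm`` or, for per-conformer
    data, ``atom_label, shift_ppm, conformer_id, energy_kJmol`` (the
    latter is Boltzmann averaged at ``temperature``).  Comma, tab or
    whitespace delimited; lines starting with '#' are ignored.
    """
    import re
    from pathlib import Path

    path = Path(path)
    rows = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = re.split(r"[,\t;]+|\s+", line)
        if parts[0].lower() in ("atom", "atom_label", "label"):
            continue
        rows.append(parts)
    if not rows:
        raise ValueError(f"empty shift table {path}")
    cid = candidate_id or path.stem
    if len(rows[0]) >= 4:
        by_conf: dict[str, tuple[float, dict[str, float]]] = {}
        for label, value, conf, energy in (r[:4] for r in rows):
            e = float(energy)
            entry = by_conf.setdefault(conf, (e, {}))
            entry[1][label] = float(value)
        block = list(by_conf.values())
        averaged = boltzmann_average(block, temperature, shielding_reference)
        atoms = sorted(averaged.items())
        return CandidateShifts(
            cid, nucleus, atoms,
            methyl_groups=methyl_groups or [],
            labile_labels=labile_labels,
            conformer_block=block,
        )
    atoms = [(r[0], float(r[1])) for r in rows]
    return CandidateShifts(
        cid, nucleus, atoms,
        methyl_groups=methyl_groups or [],
        labile_labels=labile_labels,
    )


def write_assignment_report(result: AssignmentResult, path, fmt: str = "tsv"):
    """Write atom, scaled shift, peak and error as TSV or JSON."""
    import json
    from pathlib import Path

    path = Path(path)
    rows = [
        {
            "atom": label,
            "scaled_shift_ppm": a.scaled_shift,
            "peak_ppm": a.peak_ppm,
            "error_ppm": a.error,
        }
        for label, a in sorted(result.atoms.items())
    ]
    if fmt == "json":
        path.write_text(json.dumps(
            {
                "candidate": result.candidate_id,
                "nucleus": result.nucleus,
                "scaling_stages": result.scaling_stages,
                "reassignments": result.reassignment_log,
                "atoms": rows,
            },
            indent=1,
        ))
    else:
        lines = ["atom\tscaled_shift_ppm\tpeak_ppm\terror_ppm"]
        lines += [
            f"{r['atom']}\t{r['scaled_shift_ppm']:.4f}\t{r['peak_ppm']:.4f}\t{r['error_ppm']:.4f}"
            for r in rows
        ]
        path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# Carbon orchestration
# ---------------------------------------------------------------------------

def _carbon_round(
    scaled: np.ndarray,
    labels: list[str],
    peaks: list[CarbonPeak],
    error_model: ErrorModel,
) -> dict[str, AtomAssignment]:
    positions = np.array([p.position for p in peaks])
    weights = np.array([p.weight for p in peaks])
    groups = np.array([p.amplitude_group for p in peaks])
    reps = 1
    if scaled.size > positions.size:
        reps = math.ceil(scaled.size / positions.size) + 1
    matrix = build_matrix(
        scaled, labels, positions, error_model, "C13",
        peak_weights=weights, peak_groups=groups, replications=reps,
    )
    match = assign_hungarian(matrix)
    out = {}
    for row, col in match:
        j = matrix.column_peaks[col]
        out[labels[row]] = AtomAssignment(
            peak_index=j,
            peak_ppm=float(positions[j]),
            scaled_shift=float(scaled[row]),
            error=float(scaled[row] - positions[j]),
        )
    return out


def bias_reassign(
    result: AssignmentResult,
    peaks: list[CarbonPeak],
    window: float = 10.0,
) -> AssignmentResult:
    """Rescue intense unassigned peaks near each assigned shift.

    The bias of shift i is the summed amplitude weight of unassigned
    peaks within +/- ``window`` ppm of its assigned peak, divided by the
    weight of the assigned peak itself.  Shifts with bias above one are
    reassigned in descending bias order, each to the largest-amplitude
    unassigned peak remaining in its window.
    """
    counts = result.assigned_counts(len(peaks))
    unassigned = {j for j in range(len(peaks)) if counts[j] == 0}

    biases = []
    for label, a in result.atoms.items():
        local = [j for j in unassigned if abs(peaks[j].position - a.peak_ppm) <= window]
        if not local:
            continue
        bias = sum(peaks[j].weight for j in local) / max(peaks[a.peak_index].weight, 1e-12)
        if bias > 1.0:
            biases.append((bias, label))
    biases.sort(reverse=True)

    for bias, label in biases:
        a = result.atoms[label]
        local = [j for j in unassigned if abs(peaks[j].position - a.peak_ppm) <= window]
        if not local:
            continue
        target = max(local, key=lambda j: peaks[j].amplitude)
        result.reassignment_log.append(
            f"{label}: bias {bias:.2f} -> peak at {peaks[target].position:.2f} ppm"
        )
        result.atoms[label] = AtomAssignment(
            peak_index=target,
            peak_ppm=float(peaks[target].position),
            scaled_shift=a.scaled_shift,
            error=float(a.scaled_shift - peaks[target].position),
        )
        unassigned.discard(target)

    counts = result.assigned_counts(len(peaks))
    result.unassigned_peaks = [j for j in range(len(peaks)) if counts[j] == 0]
    return result


def assign_carbons(
    shifts: CandidateShifts,
    peaks: list[CarbonPeak],
    error_model: ErrorModel,
    external_factors: tuple[float, float] = (1.0, 0.0),
    bias_window: float = 10.0,
) -> AssignmentResult:
    """Three-stage carbon assignment: external scale, internal rescale,
    bias reassignment."""
    if not peaks:
        raise ValueError("no experimental carbon peaks to assign")
    labels = shifts.labels
    order = sorted(range(len(labels)), key=lambda i: labels[i])
    labels = [labels[i] for i in order]
    calc = shifts.values[order]

    stage1 = scale_external(calc, external_factors)
    atoms = _carbon_round(stage1, labels, peaks, error_model)
    result = AssignmentResult(shifts.candidate_id, "C13", atoms)
    result.scaling_stages.append(("external", *external_factors))

    pairs = [(c, atoms[l].peak_ppm) for c, l in zip(stage1, labels)]
    slope, intercept = scale_internal(pairs)
    result.scaling_stages.append(("internal", slope, intercept))
    stage2 = (stage1 - intercept) / slope
    result.atoms = _carbon_round(stage2, labels, peaks, error_model)

    counts = result.assigned_counts(len(peaks))
    result.unassigned_peaks = [j for j in range(len(peaks)) if counts[j] == 0]
    return bias_reassign(result, peaks, bias_window)


# ---------------------------------------------------------------------------
# Proton orchestration
# ---------------------------------------------------------------------------

def _proton_round(
    scaled: dict[str, float],
    shifts: CandidateShifts,
    multiplets: list[Multiplet],
    error_model: ErrorModel,
) -> dict[str, AtomAssignment]:
    """One full proton assignment pass: methyl trios first, then the rest."""
    centers = np.array([m.center for m in multiplets])
    capacity = np.array([max(m.proton_count, 0) for m in multiplets], dtype=int)

    assignable = [l for l in scaled if l not in shifts.labile_labels]
    methyl_labels = {l for trio in shifts.methyl_groups for l in trio}
    out: dict[str, AtomAssignment] = {}

    def hungarian_on(labels: list[str], values: np.ndarray, col_peaks: list[int]) -> list[tuple[int, int]]:
        if not labels:
            return []
        positions = centers[col_peaks]
        base = error_pdf(values[:, None] - positions[None, :], error_model)
        matrix = AssignmentMatrix(
            np.atleast_2d(base), labels, col_peaks, [0] * len(col_peaks)
        )
        return assign_hungarian(matrix)

    # phase A: methyl trios, capacity consumed three protons at a time
    trios = [t for t in shifts.methyl_groups if all(l in scaled for l in t)]
    if trios:
        trio_vals = np.array([np.mean([scaled[l] for l in t]) for t in trios])
        cols = [j for j in range(len(multiplets)) for _ in range(capacity[j] // 3)]
        if len(cols) < len(trios):
            warnings.warn("insufficient 3-proton capacity for methyl groups", stacklevel=2)
            while len(cols) < len(trios):
                cols = cols + list(range(len(multiplets)))
        trio_labels = ["+".join(t) for t in trios]
        for row, col in hungarian_on(trio_labels, trio_vals, cols):
            j = cols[col]
            capacity[j] = max(capacity[j] - 3, 0)
            for l in trios[row]:
                out[l] = AtomAssignment(
                    peak_index=j,
                    peak_ppm=float(centers[j]),
                    scaled_shift=float(scaled[l]),
                    error=float(scaled[l] - centers[j]),
                )

    # phase B: remaining protons against residual capacity
    rest = [l for l in assignable if l not in methyl_labels]
    if rest:
        vals = np.array([scaled[l] for l in rest])
        cols = [j for j in range(len(multiplets)) for _ in range(capacity[j])]
        if len(cols) < len(rest):
            warnings.warn(
                "total proton capacity below proton count; relaxing capacities",
                stacklevel=2,
            )
            while len(cols) < len(rest):
                cols = cols + list(range(len(multiplets)))
        for row, col in hungarian_on(rest, vals, cols):
            j = cols[col]
            out[rest[row]] = AtomAssignment(
                peak_index=j,
                peak_ppm=float(centers[j]),
                scaled_shift=float(vals[row]),
                error=float(vals[row] - centers[j]),
            )
    return out


def assign_protons(
    shifts: CandidateShifts,
    multiplets: list[Multiplet],
    error_model: ErrorModel,
    external_factors: tuple[float, float] = (1.0, 0.0),
) -> AssignmentResult:
    """Two-stage proton assignment with the methyl pre-stage.

    External scaling, a first assignment, internal rescaling from the
    assigned pairs, then a final assignment.  No amplitude weighting,
    penalties or bias: integrals bound how often each multiplet is used.
    """
    if not multiplets:
        raise ValueError("no multiplets to assign")
    labels = sorted(shifts.labels)
    values = dict(zip(shifts.labels, shifts.values))
    stage1 = dict(
        zip(labels, scale_external(np.array([values[l] for l in labels]), external_factors))
    )
    atoms = _proton_round(stage1, shifts, multiplets, error_model)
    result = AssignmentResult(shifts.candidate_id, "H1", atoms)
    result.scaling_stages.append(("external", *external_factors))

    pairs = [(stage1[l], a.peak_ppm) for l, a in atoms.items()]
    slope, intercept = scale_internal(pairs)
    result.scaling_stages.append(("internal", slope, intercept))
    stage2 = {l: (v - intercept) / slope for l, v in stage1.items()}
    result.atoms = _proton_round(stage2, shifts, multiplets, error_model)

    counts = result.assigned_counts(len(multiplets))
    result.unassigned_peaks = [j for j in range(len(multiplets)) if counts[j] == 0]
    return result
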