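"""Native-water identification and saturation-test metrics.

A crystallographic water is *bridging* when its oxygen lies within
``bridging_cutoff`` (3 Å) of both a ligand heavy atom and a protein heavy
atom, and *local* when it lies within ``local_cutoff`` (5 Å) of any ligand
atom. The saturation test runs placement on the unperturbed native pose
and asks, for every native bridging water, how far away the nearest
predicted water is; a native is *recaptured* when that distance is at
most ``success_cutoff`` (1.4 Å, roughly half a water diameter). Matching
is per-native nearest (many-to-one) — over-prediction is counted
separately, never penalized in the recapture statistic.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .errors import BridgewaterError
from .placement import PlacedWater
from .structio import Atom, InterfaceComplex, coords

__all__ = [
    "EvalParams",
    "SaturationReport",
    "AggregateSummary",
    "DatasetEntry",
    "FilterResult",
    "find_native_waters",
    "score_saturation",
    "aggregate_reports",
    "filter_dataset",
    "match_one_to_one",
    "NUCLEIC_RESIDUE_NAMES",
]

NUCLEIC_RESIDUE_NAMES = frozenset({"A", "C", "G", "U", "T", "DA", "DC", "DG", "DT", "DU"})


@dataclass(frozen=True)
class EvalParams:
    bridging_cutoff: float = 3.0
    local_cutoff: float = 5.0
    success_cutoff: float = 1.4

    def __post_init__(self) -> None:
        if min(self.bridging_cutoff, self.local_cutoff, self.success_cutoff) <= 0:
            raise ValueError("all cutoffs must be > 0")
        if self.bridging_cutoff > self.local_cutoff:
            raise ValueError("bridging_cutoff must be <= local_cutoff")


@dataclass
class SaturationReport:
    """Per-complex recapture statistics.

    ``per_native_nearest`` pairs each native bridging water id with the
    distance to its nearest predicted water (inf when nothing was
    placed). ``mean_nearest_dist`` is None when the complex has no native
    bridging waters.
    """

    source_id: str
    n_native_bridging: int
    n_native_local: int
    n_placed: int
    per_native_nearest: list[tuple[str, float]]
    n_recaptured: int
    mean_nearest_dist: float | None

    @property
    def overprediction(self) -> int:
        return self.n_placed - self.n_native_bridging


@dataclass
class AggregateSummary:
    n_complexes: int
    n_native_bridging: int
    n_native_local: int
    n_placed: int
    n_recaptured: int
    recapture_fraction: float | None  # None when no natives at all
    overprediction_per_complex: list[int]
    mean_overprediction: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def find_native_waters(
    complex_: InterfaceComplex, params: EvalParams = EvalParams()
) -> tuple[list[Atom], list[Atom]]:
    """Split crystallographic waters into (bridging, local) lists.

    Distances are water-oxygen to heavy-atom; bridging waters are a
    subset of local waters by construction (bridging_cutoff <=
    local_cutoff and a bridging water is within the ligand cutoff).
    """
    waters = complex_.water_oxygens
    if not waters:
        return [], []
    wxyz = coords(waters)
    lig = coords(complex_.ligand_atoms)
    prot = coords(complex_.protein_atoms)
    d_lig = cdist(wxyz, lig).min(axis=1)
    d_prot = (cdist(wxyz, prot).min(axis=1) if len(prot)
              else np.full(len(waters), np.inf))
    bridging_mask = (d_lig <= params.bridging_cutoff) & (d_prot <= params.bridging_cutoff)
    local_mask = d_lig <= params.local_cutoff
    bridging = [w for w, m in zip(waters, bridging_mask) if m]
    local = [w for w, m in zip(waters, local_mask) if m]
    return bridging, local


def score_saturation(
    native_bridging: Sequence[Atom],
    placed: Sequence[PlacedWater],
    params: EvalParams = EvalParams(),
    *,
    source_id: str = "",
    n_native_local: int = 0,
) -> SaturationReport:
    """Distance from each native bridging water to its nearest placed water.

    One placed water may recapture several natives; with no placed
    waters every per-native distance is +inf and nothing is recaptured.
    """
    per_native: list[tuple[str, float]] = []
    if native_bridging:
        nxyz = coords(list(native_bridging))
        if placed:
            pxyz = np.array([p.coord for p in placed], dtype=float)
            nearest = cdist(nxyz, pxyz).min(axis=1)
        else:
            nearest = np.full(len(native_bridging), np.inf)
        per_native = [(w.residue_id, float(d)) for w, d in zip(native_bridging, nearest)]
    n_recaptured = sum(1 for _, d in per_native if d <= params.success_cutoff)
    finite_ok = [d for _, d in per_native]
    mean_nearest = (float(np.mean(finite_ok)) if per_native else None)
    if mean_nearest is not None and math.isinf(mean_nearest):
        mean_nearest = math.inf
    return SaturationReport(
        source_id=source_id,
        n_native_bridging=len(native_bridging),
        n_native_local=n_native_local,
        n_placed=len(placed),
        per_native_nearest=per_native,
        n_recaptured=n_recaptured,
        mean_nearest_dist=mean_nearest,
    )


def aggregate_reports(reports: Sequence[SaturationReport]) -> AggregateSummary:
    """Dataset-level sums and the overall recapture fraction."""
    if not reports:
        raise BridgewaterError("no reports")
    n_native = sum(r.n_native_bridging for r in reports)
    n_rec = sum(r.n_recaptured for r in reports)
    over = [r.overprediction for r in reports]
    return AggregateSummary(
        n_complexes=len(reports),
        n_native_bridging=n_native,
        n_native_local=sum(r.n_native_local for r in reports),
        n_placed=sum(r.n_placed for r in reports),
        n_recaptured=n_rec,
        recapture_fraction=(n_rec / n_native if n_native else None),
        overprediction_per_complex=over,
        mean_overprediction=float(np.mean(over)),
    )


def match_one_to_one(
    native_bridging: Sequence[Atom],
    placed: Sequence[PlacedWater],
    params: EvalParams = EvalParams(),
) -> list[tuple[str, float]]:
    """Optional stricter metric: optimal one-to-one native/placed pairing.

    Uses a minimum-cost assignment on the distance matrix, so each
    placed water can recapture at most one native. This is NOT the
    headline recapture statistic (which is per-native nearest); it is
    provided for analyses that want false-positive-aware matching.
    Returns (native id, matched distance) for natives that got a partner.
    """
    if not native_bridging or not placed:
        return []
    nxyz = coords(list(native_bridging))
    pxyz = np.array([p.coord for p in placed], dtype=float)
    dmat = cdist(nxyz, pxyz)
    rows, cols = linear_sum_assignment(dmat)
    return [(native_bridging[i].residue_id, float(dmat[i, j]))
            for i, j in zip(rows, cols)]


@dataclass
class DatasetEntry:
    """One candidate benchmark complex with its metadata."""

    complex: InterfaceComplex
    resolution: float | None
    source_id: str = ""

    def __post_init__(self) -> None:
        if not self.source_id:
            self.source_id = self.complex.source_id


@dataclass
class FilterResult:
    accepted: list[DatasetEntry]
    rejection_counts: dict[str, int]
    rejections: list[tuple[str, str]]  # (source_id, reason)


#: order in which the curation rules are applied; the first failing rule
#: is the recorded rejection reason.
FILTER_RULES = ("dna_rna", "cofactor", "bridging_count", "resolution")


def filter_dataset(
    entries: Sequence[DatasetEntry],
    params: EvalParams = EvalParams(),
    *,
    cofactor_cutoff: float = 6.0,
    max_bridging: int = 6,
    max_resolution: float = 1.7,
) -> FilterResult:
    """Benchmark curation: drop nucleic acids, nearby cofactors, water-rich
    and low-resolution entries.

    An entry is accepted iff it has no DNA/RNA residues, no non-water
    HETATM group (other than the designated ligand) within
    ``cofactor_cutoff`` of any ligand atom, at most ``max_bridging``
    bridging waters, and resolution <= ``max_resolution``. A missing
    resolution rejects the entry with reason ``"no resolution"``.
    """
    accepted: list[DatasetEntry] = []
    rejections: list[tuple[str, str]] = []
    counts = {rule: 0 for rule in FILTER_RULES}
    counts["no resolution"] = 0

    for entry in entries:
        cx = entry.complex
        reason = None
        residue_names = {a.residue_name for a in cx.all_atoms}
        if residue_names & NUCLEIC_RESIDUE_NAMES:
            reason = "dna_rna"
        if reason is None and cx.other_atoms:
            d = cdist(coords(cx.other_atoms), coords(cx.ligand_atoms))
            if d.min() <= cofactor_cutoff:
                reason = "cofactor"
        if reason is None:
            bridging, _ = find_native_waters(cx, params)
            if len(bridging) > max_bridging:
                reason = "bridging_count"
        if reason is None:
            if entry.resolution is None:
                reason = "no resolution"
            elif entry.resolution > max_resolution:
                reason = "resolution"
        if reason is None:
            accepted.append(entry)
        else:
            counts[reason] += 1
            rejections.append((entry.source_id, reason))
    return FilterResult(accepted=accepted, rejection_counts=counts,
                        rejections=rejections)
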