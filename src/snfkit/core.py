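"""Domain types and construction of the ternary region-by-study fingerprint matrix.

A *structural fingerprint matrix* ``X`` has one row per atlas region of
interest (ROI) and one column per study.  ``X[r, s]`` is ``-1`` when study
``s`` reported a significant structural decrease in region ``r`` (reduced
grey/white-matter volume or probability), ``+1`` for a reported increase,
and ``0`` when the region was not reported as abnormal.  Absence of a
report is encoded by omission at the observation level, never by an
explicit zero observation.

Regions carry hemisphere, tissue class and one or more canonical
large-scale network memberships; a :class:`NetworkScheme` fixes the
network vocabulary and the priority order used to pick a region's
*dominant* network when it belongs to several.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CANONICAL_NETWORKS",
    "DEFAULT_PRIORITY",
    "Hemisphere",
    "Tissue",
    "Method",
    "Design",
    "Confidence",
    "ConflictPolicy",
    "RegionRecord",
    "StudyRecord",
    "Observation",
    "NetworkScheme",
    "FingerprintMatrix",
    "ValidationIssue",
    "SnfError",
    "UnknownIdentifierError",
    "SignConflictError",
    "MatrixFormatError",
    "build_matrix",
    "validate_matrix",
    "subset_matrix",
]

#: Canonical large-scale network vocabulary: default mode, salience,
#: frontoparietal control, limbic/memory, sensorimotor/dorsal-attention,
#: interhemispheric (callosal), brainstem/cerebellar.
CANONICAL_NETWORKS: tuple[str, ...] = ("DMN", "SAL", "FPN", "LIM", "SMN", "CAL", "BSC")

#: Default dominant-affiliation priority for multi-network regions.
DEFAULT_PRIORITY: tuple[str, ...] = ("DMN", "LIM", "SAL", "FPN", "SMN", "CAL", "BSC")


class SnfError(Exception):
    """Base class for fingerprint-domain errors."""


class UnknownIdentifierError(SnfError, KeyError):
    """An roi_id, study_id or network id does not resolve."""

    def __str__(self) -> str:  # KeyError quotes its message otherwise
        return self.args[0] if self.args else ""


class SignConflictError(SnfError, ValueError):
    """Opposite-direction observations for one (region, study) cell."""


class MatrixFormatError(SnfError, ValueError):
    """A delimited file does not conform to the declared dialect."""


class Hemisphere(enum.Enum):
    LEFT = "L"
    RIGHT = "R"
    BILATERAL = "B"


class Tissue(enum.Enum):
    GM = "GM"
    WM = "WM"
    MIXED = "MIXED"


class Method(enum.Enum):
    """Morphometric method of a source study."""

    VBM = "VBM"
    VOLUMETRY = "VOLUMETRY"
    GM_PROB = "GM_PROB"
    WM_PROB = "WM_PROB"
    TBM = "TBM"


class Design(enum.Enum):
    CROSS_SECTIONAL = "CROSS_SECTIONAL"
    LONGITUDINAL = "LONGITUDINAL"


class Confidence(enum.Enum):
    """Provenance of a study column in a packaged fixture."""

    NARRATIVE = "NARRATIVE"
    RECONSTRUCTED_LOW_CONFIDENCE = "RECONSTRUCTED_LOW_CONFIDENCE"


class ConflictPolicy(enum.Enum):
    """How opposite-sign observations for one cell are resolved."""

    ERROR = "error"
    MAJORITY = "majority"


@dataclass(frozen=True)
class RegionRecord:
    """An atlas region of interest.

    ``networks`` is a non-empty ordered set (stored as a tuple, duplicates
    removed, first occurrence wins) of network identifiers.  Regions that
    span several functional systems (e.g. rostral anterior cingulate) list
    every system they belong to.
    """

    roi_id: str
    label: str
    hemisphere: Hemisphere
    tissue: Tissue
    networks: tuple[str, ...]

    def __post_init__(self) -> None:
        seen: dict[str, None] = dict.fromkeys(self.networks)
        object.__setattr__(self, "networks", tuple(seen))
        if not self.networks:
            raise ValueError(f"region {self.roi_id!r} has an empty network set")
        object.__setattr__(self, "hemisphere", Hemisphere(self.hemisphere))
        object.__setattr__(self, "tissue", Tissue(self.tissue))


@dataclass(frozen=True)
class StudyRecord:
    """One source study (a column of the fingerprint matrix)."""

    study_id: str
    citation: str
    method: Method
    design: Design
    confidence: Confidence = Confidence.NARRATIVE

    def __post_init__(self) -> None:
        object.__setattr__(self, "method", Method(self.method))
        object.__setattr__(self, "design", Design(self.design))
        object.__setattr__(self, "confidence", Confidence(self.confidence))


@dataclass(frozen=True)
class Observation:
    """A single reported abnormality: region, study, direction in {-1, +1}.

    A direction of 0 is rejected: a region not reported abnormal is simply
    absent from the observation list.
    """

    roi_id: str
    study_id: str
    direction: int

    def __post_init__(self) -> None:
        if self.direction not in (-1, 1):
            raise ValueError(
                f"direction must be -1 or +1, got {self.direction!r} "
                f"for ({self.roi_id}, {self.study_id})"
            )


@dataclass(frozen=True)
class NetworkScheme:
    """Network vocabulary, per-ROI membership and dominant-network priority.

    ``priority`` must be a permutation of ``network_ids``; a region's
    dominant network is its first membership in priority order.
    """

    network_ids: tuple[str, ...]
    membership: Mapping[str, tuple[str, ...]]
    priority: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.priority:
            object.__setattr__(self, "priority", tuple(self.network_ids))
        if sorted(self.priority) != sorted(self.network_ids):
            raise ValueError("priority must be a permutation of network_ids")
        known = set(self.network_ids)
        for roi_id, nets in self.membership.items():
            missing = [k for k in nets if k not in known]
            if missing:
                raise ValueError(
                    f"region {roi_id!r} references networks {missing} "
                    "absent from network_ids"
                )

    @classmethod
    def from_regions(
        cls,
        regions: Sequence[RegionRecord],
        network_ids: Sequence[str] = CANONICAL_NETWORKS,
        priority: Sequence[str] = DEFAULT_PRIORITY,
    ) -> "NetworkScheme":
        return cls(
            network_ids=tuple(network_ids),
            membership={r.roi_id: r.networks for r in regions},
            priority=tuple(priority),
        )

    def require(self, network: str) -> str:
        if network not in self.network_ids:
            raise UnknownIdentifierError(
                f"unknown network id {network!r}; scheme defines {self.network_ids}"
            )
        return network

    def members(self, network: str) -> tuple[str, ...]:
        """ROI ids assigned to ``network`` (the region set R_k), in membership order."""
        self.require(network)
        return tuple(r for r, nets in self.membership.items() if network in nets)

    def dominant(self, roi_id: str) -> str:
        """First of the region's networks in priority order."""
        try:
            nets = self.membership[roi_id]
        except KeyError:
            raise UnknownIdentifierError(f"unknown roi_id {roi_id!r}") from None
        for k in self.priority:
            if k in nets:
                return k
        raise ValueError(f"region {roi_id!r} has no network in the priority order")


@dataclass(frozen=True)
class FingerprintMatrix:
    """The ternary region-by-study matrix with its ordered axes.

    ``entries`` is an ``int8`` array of shape ``(len(regions), len(studies))``
    with values in ``{-1, 0, +1}``.  Row ``i`` corresponds to ``regions[i]``
    and column ``j`` to ``studies[j]``.
    """

    regions: tuple[RegionRecord, ...]
    studies: tuple[StudyRecord, ...]
    entries: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.entries)
        if arr.shape != (len(self.regions), len(self.studies)):
            raise ValueError(
                f"entries shape {arr.shape} does not match "
                f"{len(self.regions)} regions x {len(self.studies)} studies"
            )
        object.__setattr__(self, "entries", np.array(arr, dtype=np.int8, copy=True))
        self.entries.setflags(write=False)
        object.__setattr__(self, "regions", tuple(self.regions))
        object.__setattr__(self, "studies", tuple(self.studies))

    @property
    def roi_ids(self) -> tuple[str, ...]:
        return tuple(r.roi_id for r in self.regions)

    @property
    def study_ids(self) -> tuple[str, ...]:
        return tuple(s.study_id for s in self.studies)

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def n_studies(self) -> int:
        return len(self.studies)

    def region_index(self, roi_id: str) -> int:
        try:
            return self.roi_ids.index(roi_id)
        except ValueError:
            raise UnknownIdentifierError(f"unknown roi_id {roi_id!r}") from None

    def to_frame(self) -> pd.DataFrame:
        """Entries as a DataFrame indexed by roi_id with study_id columns."""
        return pd.DataFrame(
            self.entries.astype(int),
            index=pd.Index(self.roi_ids, name="roi_id"),
            columns=list(self.study_ids),
        )

    def observations(self) -> list[Observation]:
        """Re-extract the consolidated non-zero cells as observations."""
        rows, cols = np.nonzero(self.entries)
        return [
            Observation(self.regions[i].roi_id, self.studies[j].study_id,
                        int(self.entries[i, j]))
            for i, j in zip(rows.tolist(), cols.tolist())
        ]


@dataclass(frozen=True)
class ValidationIssue:
    severity: str  # "ERROR" | "WARNING"
    code: str
    message: str
    location: str = ""


def build_matrix(
    observations: Iterable[Observation],
    regions: Sequence[RegionRecord],
    studies: Sequence[StudyRecord],
    conflict_policy: ConflictPolicy | str = ConflictPolicy.ERROR,
) -> FingerprintMatrix:
    """Assemble the ternary matrix from per-study abnormality observations.

    Multiple same-sign observations for one (region, study) cell — e.g.
    several significant clusters falling in the same atlas region — are
    consolidated into a single entry.  Opposite-sign observations are
    resolved by ``conflict_policy``: ``ERROR`` raises
    :class:`SignConflictError`; ``MAJORITY`` keeps the more frequent sign
    and raises on an exact tie.

    Raises
    ------
    UnknownIdentifierError
        If an observation references an undeclared roi_id or study_id.
    SignConflictError
        On an opposite-sign conflict under ERROR, or a tie under MAJORITY.
    """
    policy = ConflictPolicy(conflict_policy)
    row_of = {r.roi_id: i for i, r in enumerate(regions)}
    col_of = {s.study_id: j for j, s in enumerate(studies)}
    if len(row_of) != len(regions):
        dupes = [k for k, n in Counter(r.roi_id for r in regions).items() if n > 1]
        raise ValueError(f"duplicate roi_id(s) in region list: {dupes}")
    if len(col_of) != len(studies):
        dupes = [k for k, n in Counter(s.study_id for s in studies).items() if n > 1]
        raise ValueError(f"duplicate study_id(s) in study list: {dupes}")

    signs: dict[tuple[int, int], Counter] = {}
    for obs in observations:
        if obs.roi_id not in row_of:
            raise UnknownIdentifierError(f"observation references unknown roi_id {obs.roi_id!r}")
        if obs.study_id not in col_of:
            raise UnknownIdentifierError(
                f"observation references unknown study_id {obs.study_id!r}"
            )
        cell = (row_of[obs.roi_id], col_of[obs.study_id])
        signs.setdefault(cell, Counter())[obs.direction] += 1

    entries = np.zeros((len(regions), len(studies)), dtype=np.int8)
    conflicts: list[tuple[str, str]] = []
    for (i, j), counts in signs.items():
        if len(counts) == 1:
            entries[i, j] = next(iter(counts))
            continue
        pair = (regions[i].roi_id, studies[j].study_id)
        if policy is ConflictPolicy.ERROR or counts[-1] == counts[1]:
            conflicts.append(pair)
        else:
            entries[i, j] = -1 if counts[-1] > counts[1] else 1
    if conflicts:
        kind = "unresolvable (tied)" if policy is ConflictPolicy.MAJORITY else "opposite-sign"
        raise SignConflictError(
            f"{kind} observation conflict for (region, study) pairs: {sorted(conflicts)}"
        )
    return FingerprintMatrix(tuple(regions), tuple(studies), entries)


def validate_matrix(m: FingerprintMatrix) -> list[ValidationIssue]:
    """Check domain invariants, returning issues instead of raising.

    ERROR issues: entries outside {-1, 0, +1}, duplicate roi_id/study_id,
    a region with an empty network set.  WARNING issues: all-zero rows
    (regions never reported abnormal are permitted but flagged).
    An empty list means the matrix is fully valid.
    """
    issues: list[ValidationIssue] = []
    bad = np.argwhere(~np.isin(m.entries, (-1, 0, 1)))
    for i, j in bad.tolist():
        issues.append(ValidationIssue(
            "ERROR", "entry_domain",
            f"entry ({m.regions[i].roi_id}, {m.studies[j].study_id}) = "
            f"{int(m.entries[i, j])} outside {{-1, 0, +1}}",
            f"row {i}, column {j}",
        ))
    for kind, ids in (("roi_id", m.roi_ids), ("study_id", m.study_ids)):
        for ident, n in Counter(ids).items():
            if n > 1:
                issues.append(ValidationIssue(
                    "ERROR", f"duplicate_{kind}",
                    f"{kind} {ident!r} appears {n} times", ident))
    for i, region in enumerate(m.regions):
        # frozen dataclass normally rejects this at construction; guard anyway
        if not region.networks:
            issues.append(ValidationIssue(
                "ERROR", "empty_networks",
                f"region {region.roi_id!r} has an empty network set",
                region.roi_id))
    for i in np.flatnonzero(~m.entries.any(axis=1)).tolist():
        issues.append(ValidationIssue(
            "WARNING", "all_zero_row",
            f"region {m.regions[i].roi_id!r} has no abnormal report in any study",
            m.regions[i].roi_id))
    return issues


def subset_matrix(
    m: FingerprintMatrix,
    scheme: NetworkScheme | None = None,
    network: str | None = None,
    tissue: Tissue | str | None = None,
) -> FingerprintMatrix:
    """Row-subset to one network's region set R_k and/or one tissue class.

    The study axis and region order are preserved.  With no filters the
    matrix is returned unchanged (same object).
    """
    if network is None and tissue is None:
        return m
    keep = np.ones(m.n_regions, dtype=bool)
    if network is not None:
        if scheme is None:
            raise ValueError("a NetworkScheme is required to subset by network")
        scheme.require(network)
        keep &= np.array([network in r.networks for r in m.regions])
    if tissue is not None:
        tissue = Tissue(tissue)
        keep &= np.array([r.tissue is tissue for r in m.regions])
    idx = np.flatnonzero(keep)
    return FingerprintMatrix(
        tuple(m.regions[i] for i in idx), m.studies, m.entries[idx, :]
    )
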