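"""Planted-network generative model for fingerprint matrices.

Used to validate the pipeline on data with known ground truth: regions
are partitioned into synthetic networks, and each (region, study) cell is
an independent Bernoulli draw.  A region in network ``k`` is reported
abnormal in study ``s`` with probability ``p_k * eta_s`` (network
detectability times study sensitivity); given an abnormal report, the
direction is a decrease with probability ``q_k`` and an increase
otherwise.  So in expectation the load rate recovers ``p_k`` and the mean
direction satisfies ``D_k = 1 - 2 q_k``.

``study_sensitivity`` may be a scalar, a per-study vector, or a
(network x study) matrix; the matrix form supports network-exclusive
study panels (a study that only ever reports one network's regions),
the regime used for planted-module recovery tests.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .core import (
    Confidence,
    Design,
    FingerprintMatrix,
    Hemisphere,
    Method,
    NetworkScheme,
    RegionRecord,
    StudyRecord,
    Tissue,
)
from .metrics import mean_direction, total_abnormal_load

__all__ = [
    "PlantedNetwork",
    "SyntheticSpec",
    "PlantedTruth",
    "generate_fingerprint",
    "recover_parameters",
]


@dataclass(frozen=True)
class PlantedNetwork:
    """One synthetic network: size, detection probability, loss probability."""

    network_id: str
    region_count: int
    detect_prob: float  # p_k: P(cell non-zero) before study sensitivity
    loss_prob: float    # q_k: P(direction = -1 | non-zero)

    def __post_init__(self) -> None:
        if self.region_count < 1:
            raise ValueError(f"region_count must be >= 1, got {self.region_count}")
        if not 0.0 <= self.detect_prob <= 1.0:
            raise ValueError(f"detect_prob must be in [0, 1], got {self.detect_prob}")
        if not 0.0 <= self.loss_prob <= 1.0:
            raise ValueError(f"loss_prob must be in [0, 1], got {self.loss_prob}")


@dataclass(frozen=True)
class SyntheticSpec:
    networks: tuple[PlantedNetwork, ...]
    n_studies: int
    study_sensitivity: np.ndarray = None  # scalar/vector/matrix; defaults to 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_studies < 1:
            raise ValueError(f"n_studies must be >= 1, got {self.n_studies}")
        object.__setattr__(self, "networks", tuple(self.networks))
        eta = self.study_sensitivity
        eta = np.ones(self.n_studies) if eta is None else np.asarray(eta, dtype=float)
        if eta.ndim == 0:
            eta = np.full(self.n_studies, float(eta))
        if eta.ndim == 1:
            if eta.shape != (self.n_studies,):
                raise ValueError(
                    f"study_sensitivity length {eta.shape[0]} != n_studies {self.n_studies}"
                )
            eta = np.tile(eta, (len(self.networks), 1))
        if eta.shape != (len(self.networks), self.n_studies):
            raise ValueError(
                f"study_sensitivity shape {eta.shape} incompatible with "
                f"{len(self.networks)} networks x {self.n_studies} studies"
            )
        if np.any(eta < 0.0) or np.any(eta > 1.0):
            raise ValueError("study sensitivities must lie in [0, 1]")
        p = np.array([net.detect_prob for net in self.networks])
        if np.any(p[:, None] * eta > 1.0 + 1e-12):
            raise ValueError("detect_prob * sensitivity exceeds 1 for some cell")
        eta.setflags(write=False)
        object.__setattr__(self, "study_sensitivity", eta)

    @property
    def network_ids(self) -> tuple[str, ...]:
        return tuple(net.network_id for net in self.networks)


@dataclass(frozen=True)
class PlantedTruth:
    """Ground-truth assignment and parameters behind a synthetic matrix."""

    spec: SyntheticSpec
    assignment: Mapping[str, str]  # roi_id -> network_id
    checksum: str                  # sha256 of the realised entries

    def scheme(self) -> NetworkScheme:
        return NetworkScheme(
            network_ids=self.spec.network_ids,
            membership={roi: (net,) for roi, net in self.assignment.items()},
            priority=self.spec.network_ids,
        )


def generate_fingerprint(spec: SyntheticSpec) -> tuple[FingerprintMatrix, PlantedTruth]:
    """Draw one matrix from the planted-network model.

    Reproducible: the same spec (including seed) yields a bitwise
    identical matrix; each (region, study) cell consumes a fixed position
    in the random stream, so the realisation is a deterministic function
    of the seed and the spec dimensions.
    """
    regions: list[RegionRecord] = []
    row_network: list[int] = []
    for ki, net in enumerate(spec.networks):
        for i in range(net.region_count):
            regions.append(RegionRecord(
                roi_id=f"{net.network_id}_r{i + 1:02d}",
                label=f"synthetic region {i + 1} of {net.network_id}",
                hemisphere=Hemisphere.BILATERAL,
                tissue=Tissue.GM,
                networks=(net.network_id,),
            ))
            row_network.append(ki)
    studies = tuple(
        StudyRecord(
            study_id=f"s{j + 1:02d}",
            citation=f"synthetic study {j + 1}",
            method=Method.VBM,
            design=Design.CROSS_SECTIONAL,
            confidence=Confidence.NARRATIVE,
        )
        for j in range(spec.n_studies)
    )
    p = np.array([net.detect_prob for net in spec.networks])
    q = np.array([net.loss_prob for net in spec.networks])
    rows = np.array(row_network)
    cell_p = p[rows][:, None] * spec.study_sensitivity[rows, :]
    cell_q = np.broadcast_to(q[rows][:, None], cell_p.shape)

    rng = np.random.default_rng(spec.seed)
    u = rng.random(cell_p.shape)
    v = rng.random(cell_p.shape)
    entries = np.where(u < cell_p, np.where(v < cell_q, -1, 1), 0).astype(np.int8)

    matrix = FingerprintMatrix(tuple(regions), studies, entries)
    truth = PlantedTruth(
        spec=spec,
        assignment={r.roi_id: spec.networks[k].network_id
                    for r, k in zip(regions, row_network)},
        checksum=hashlib.sha256(np.ascontiguousarray(entries).tobytes()).hexdigest(),
    )
    return matrix, truth


def recover_parameters(
    m: FingerprintMatrix, truth: PlantedTruth, scheme: NetworkScheme | None = None
) -> pd.DataFrame:
    """Moment estimates of (p_k, q_k) from a realised matrix.

    p_hat = L_k / (|R_k| |S| mean(eta_k)) and q_hat = (1 - D_k) / 2, each
    with its binomial standard error.  q_hat is NaN for a network with no
    abnormal entries.  Columns: ``network, p_true, p_hat, p_se, q_true,
    q_hat, q_se``.
    """
    scheme = truth.scheme() if scheme is None else scheme
    if set(scheme.network_ids) != set(truth.spec.network_ids):
        raise ValueError("scheme does not match the planted assignment")
    rows = []
    for ki, net in enumerate(truth.spec.networks):
        load = total_abnormal_load(m, scheme, net.network_id)
        n_cells = net.region_count * m.n_studies
        eta_mean = float(truth.spec.study_sensitivity[ki].mean())
        p_hat = load / (n_cells * eta_mean) if eta_mean > 0 else math.nan
        p_se = (math.sqrt(max(p_hat * (1 - p_hat), 0.0) / n_cells) / eta_mean
                if eta_mean > 0 else math.nan)
        if load > 0:
            q_hat = (1.0 - mean_direction(m, scheme, net.network_id)) / 2.0
            q_se = math.sqrt(max(q_hat * (1 - q_hat), 0.0) / load)
        else:
            q_hat = q_se = math.nan
        rows.append({
            "network": net.network_id,
            "p_true": net.detect_prob, "p_hat": p_hat, "p_se": p_se,
            "q_true": net.loss_prob, "q_hat": q_hat, "q_se": q_se,
        })
    return pd.DataFrame(rows)
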