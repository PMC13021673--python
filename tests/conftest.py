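import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from snfkit.core import (
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

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_region(roi_id: str, networks=("DMN",), hemisphere=Hemisphere.BILATERAL,
                tissue=Tissue.GM) -> RegionRecord:
    return RegionRecord(roi_id=roi_id, label=roi_id.replace("_", " "),
                        hemisphere=hemisphere, tissue=tissue,
                        networks=tuple(networks))


def make_study(study_id: str, method=Method.VBM,
               design=Design.CROSS_SECTIONAL) -> StudyRecord:
    return StudyRecord(study_id=study_id, citation=f"study {study_id}",
                       method=method, design=design,
                       confidence=Confidence.NARRATIVE)


def make_matrix(entries, networks_per_region=None) -> FingerprintMatrix:
    """A FingerprintMatrix over generic regions r1..rn and studies s1..sm."""
    entries = np.asarray(entries)
    n, m = entries.shape
    if networks_per_region is None:
        networks_per_region = [("DMN",)] * n
    regions = tuple(make_region(f"r{i + 1}", networks_per_region[i]) for i in range(n))
    studies = tuple(make_study(f"s{j + 1}") for j in range(m))
    return FingerprintMatrix(regions, studies, entries)


def random_matrix(rng: np.random.Generator, n_regions: int, n_studies: int,
                  networks=("DMN", "SAL", "FPN"), p_nonzero: float = 0.4):
    """Random ternary matrix with random (possibly multi-) network memberships."""
    entries = rng.choice([-1, 0, 1], size=(n_regions, n_studies),
                         p=[p_nonzero / 2, 1 - p_nonzero, p_nonzero / 2])
    memberships = []
    for _ in range(n_regions):
        k = int(rng.integers(1, len(networks) + 1))
        idx = rng.choice(len(networks), size=k, replace=False)
        memberships.append(tuple(networks[i] for i in sorted(idx)))
    m = make_matrix(entries, memberships)
    scheme = NetworkScheme.from_regions(m.regions, network_ids=networks,
                                        priority=networks)
    return m, scheme


@pytest.fixture
def toy():
    """Three regions x three studies with networks k1={r1,r2}, k2={r3}.

    entries: r1:[-1,-1,0], r2:[-1,0,+1], r3:[0,0,-1].
    """
    m = make_matrix(
        [[-1, -1, 0], [-1, 0, 1], [0, 0, -1]],
        networks_per_region=[("k1",), ("k1",), ("k2",)],
    )
    scheme = NetworkScheme.from_regions(m.regions, network_ids=("k1", "k2"),
                                        priority=("k1", "k2"))
    return m, scheme


@pytest.fixture(scope="session")
def fixture_corpus():
    from snfkit.fixture import mtbi_fixture

    return mtbi_fixture()
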