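"""The packaged mild-TBI fingerprint corpus.

A reconstruction of a ten-study T1-weighted structural-MRI synthesis:
35 atlas regions by 10 studies, ternary-coded, with hemisphere, tissue
and canonical-network metadata.  Nine study columns are coded from
explicit per-study region enumerations; the tenth study's findings were
not enumerated region-by-region in the source narrative, so its column
is a low-confidence reconstruction and is flagged
``RECONSTRUCTED_LOW_CONFIDENCE`` in the study metadata.  A provenance
table maps every non-zero cell to a source-sentence tag.
"""

from __future__ import annotations

import shutil
from importlib import resources
from pathlib import Path

import pandas as pd

from .core import FingerprintMatrix, NetworkScheme
from .io import read_fingerprint

__all__ = ["mtbi_fixture", "mtbi_provenance", "materialize_fixture", "FIXTURE_FILES"]

FIXTURE_FILES = (
    "mtbi_matrix.csv", "mtbi_regions.tsv", "mtbi_studies.tsv", "mtbi_provenance.tsv",
)


def _data_dir():
    return resources.files("snfkit") / "data"


def mtbi_fixture() -> tuple[FingerprintMatrix, NetworkScheme]:
    """Load the packaged 35-region x 10-study mild-TBI matrix and scheme."""
    with resources.as_file(_data_dir()) as d:
        return read_fingerprint(
            d / "mtbi_matrix.csv", d / "mtbi_regions.tsv", d / "mtbi_studies.tsv")


def mtbi_provenance() -> pd.DataFrame:
    """Per-cell provenance: roi_id, study_id, source_sentence_tag, confidence."""
    with resources.as_file(_data_dir() / "mtbi_provenance.tsv") as p:
        return pd.read_csv(p, sep="\t", dtype=str)


def materialize_fixture(out_dir: str | Path) -> list[Path]:
    """Copy the four fixture files into ``out_dir``; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    with resources.as_file(_data_dir()) as d:
        for name in FIXTURE_FILES:
            paths.append(Path(shutil.copyfile(d / name, out / name)))
    return paths
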