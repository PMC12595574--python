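"""Packaged study data: the family-physician-team motivator matrix.

Ships the published 15-factor direct-relation matrix (panel mean of 20
experts rating motivators for integrated-care delivery by family physician
teams in urban China) together with its factor catalog. Four factor labels
were not transcribed in the source text and carry explicit placeholder
labels; real labels can be supplied via a user catalog instead.
"""

from __future__ import annotations

from importlib.resources import files

from dematelkit.catalog import FactorCatalog
from dematelkit.io import read_catalog, read_matrix_csv
from dematelkit.panel import DirectRelationMatrix, validate_direct_matrix

_DATA = files("dematelkit") / "data"


def load_fpt_motivator_catalog() -> FactorCatalog:
    """The 15-motivator catalog (F1..F15) of the family-physician-team study."""
    return read_catalog(_DATA / "fpt_factors.json")


def load_fpt_motivator_study() -> DirectRelationMatrix:
    """The published 15×15 direct-relation matrix (panel mean, 2-decimal values)."""
    catalog = load_fpt_motivator_catalog()
    values, _ = read_matrix_csv(_DATA / "fpt_direct_relation.csv", catalog)
    return validate_direct_matrix(values, catalog, m_experts=20)
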