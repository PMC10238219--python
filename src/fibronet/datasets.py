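"""Access to the committed fixture dataset.

The fixture is a small deterministic synthetic dataset (30 genes, 12
metabolites, 2 phenotype parameters, 5 groups x 3 samples, seed 1) written
by the generator itself; it is used in unit tests and documentation
examples.  ``load_fixture`` reads the committed files; the generator
reproduces them bit-exactly from :func:`fibronet.simulate.fixture_config`.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from . import io
from .matrix import OmicsMatrix, StudyDesign


def fixture_dir() -> Path:
    return Path(str(resources.files("fibronet") / "data" / "fixture"))


def load_fixture() -> dict:
    """Load the committed fixture: counts, raw metabolites, phenotypes,
    design, and the planted module maps."""
    d = fixture_dir()
    return {
        "counts": io.read_matrix(d / "counts.tsv", "counts"),
        "metabolites": io.read_matrix(d / "metabolites.tsv", "relative_peak_area"),
        "phenotypes": io.read_matrix(d / "phenotypes.tsv", "phenotype"),
        "design": io.read_design(d / "design.tsv"),
        "gene_modules": {k: int(next(iter(v)))
                         for k, v in io.read_feature_map(d / "gene_modules.tsv").items()},
        "metabolite_modules": {k: int(next(iter(v)))
                               for k, v in io.read_feature_map(d / "metabolite_modules.tsv").items()},
    }
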