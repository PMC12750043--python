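"""Packaged target registries (CASP16 oligomer and hybrid target overviews)."""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_oligomer_targets", "load_hybrid_targets"]


def _load(name: str) -> pd.DataFrame:
    with resources.files("oligoscore.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_oligomer_targets() -> pd.DataFrame:
    """The 40 CASP16 oligomer targets: stoichiometry, category, 95% quantiles
    of DockQ and ICS over submissions, and phase/CAPRI participation flags."""
    return _load("casp16_oligomer_targets.tsv")


def load_hybrid_targets() -> pd.DataFrame:
    """The CASP16 protein-nucleic-acid hybrid targets (ICS95 and flags)."""
    return _load("casp16_hybrid_targets.tsv")
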