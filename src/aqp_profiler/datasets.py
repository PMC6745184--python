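"""Bundled published tables for the E. salsugineum aquaporin family.

``sdp_observations`` carries the per-protein, per-substrate SDP residue
strings of the published family survey; ``structural_features`` the
per-protein structural summary (length, TM count, MW, pI, NPA motifs,
ar/R filter, Froger's positions).  These are observation tables used as
fixtures and rule inputs, not outputs of this package.
"""

from __future__ import annotations

from importlib import resources
from io import StringIO

import pandas as pd


def _read(name: str) -> pd.DataFrame:
    text = resources.files("aqp_profiler.data").joinpath(name).read_text()
    return pd.read_csv(StringIO(text), sep="\t")


def sdp_observations() -> pd.DataFrame:
    """Published per-protein SDP residues, one row per (protein, substrate)."""
    return _read("esaqp_sdp_observations.tsv")


def structural_features() -> pd.DataFrame:
    """Published structural summary of the 35 EsAQP proteins."""
    return _read("esaqp_structural_features.tsv")


def default_anchor_panel():
    """The bundled default reference-anchor panel (synthetic).

    Eight anchors spanning PIP/TIP/NIP/SIP, generated deterministically by
    :func:`aqp_profiler.synthetic.make_reference_panel` (seed 0) and
    stored in the package's anchor-table format.  These are synthetic
    stand-in sequences with planted features, not curated natural AQPs;
    swap in a curated table for real-data classification.
    """
    from .seqio import read_anchor_table

    path = resources.files("aqp_profiler.data").joinpath("synthetic_anchor_panel.tsv")
    with resources.as_file(path) as p:
        return read_anchor_table(p)
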