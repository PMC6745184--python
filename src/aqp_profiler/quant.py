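"""Expression quantification (dCt / ddCt) and oocyte water permeability.

qPCR: organ-level abundance uses the dCt statistic 2^(Ct_ref - Ct_gene)
so larger values mean higher expression; stress fold changes use the
classical 2^-ddCt.  Technical replicates are averaged within each
biological replicate before any statistic.

Oocyte swelling: volumes come from the measured cross-sectional area under
a spherical model, and the osmotic water permeability coefficient is

    Pf = V0 * [d(V/V0)/dt] / (S0 * Vw * (Osm_in - Osm_out)),

with Vw = 18 cm^3/mol the molar volume of water and the initial slope
estimated over the first 10 minutes.  With areas in cm^2, time in minutes
(converted to seconds internally) and osmolalities in mol/cm^3, Pf is in
cm/s.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import pi, sqrt

import numpy as np
import pandas as pd
from scipy import stats

VW_WATER = 18.0  # molar volume of water, cm^3/mol


# ---------------------------------------------------------------------------
# qPCR

@dataclass
class CtTable:
    """qPCR threshold cycles: rows of (gene, sample, bio_rep, tech_rep, ct).

    The reference gene must be measured in every sample; Ct values are
    positive cycle numbers.
    """

    data: pd.DataFrame
    reference_gene: str

    REQUIRED = ("gene", "sample", "bio_rep", "tech_rep", "ct")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"Ct table missing column(s) {missing}")
        if (self.data["ct"] <= 0).any():
            raise ValueError("Ct values must be positive")
        samples = set(self.data["sample"])
        ref_samples = set(self.data.loc[self.data["gene"] == self.reference_gene,
                                        "sample"])
        if samples - ref_samples:
            raise ValueError(
                f"reference gene {self.reference_gene!r} missing from "
                f"sample(s) {sorted(samples - ref_samples)}")

    @property
    def genes(self) -> list[str]:
        return sorted(g for g in self.data["gene"].unique()
                      if g != self.reference_gene)

    @property
    def samples(self) -> list[str]:
        return sorted(self.data["sample"].unique())

    def mean_ct(self, gene: str, sample: str) -> float:
        """Mean Ct: technical replicates averaged within biological ones."""
        sel = self.data[(self.data["gene"] == gene) & (self.data["sample"] == sample)]
        if sel.empty:
            raise KeyError(f"no Ct rows for gene {gene!r} in sample {sample!r}")
        return float(sel.groupby("bio_rep")["ct"].mean().mean())


def read_ct_table(path, reference_gene: str) -> CtTable:
    """Read a Ct CSV with columns gene, sample, bio_rep, tech_rep, ct."""
    return CtTable(pd.read_csv(path), reference_gene)


def relative_expression_dct(table: CtTable, gene: str, sample: str) -> float:
    """2^(mean Ct_reference - mean Ct_gene): abundance relative to reference.

    One cycle below the reference doubles the value.
    """
    dct = table.mean_ct(table.reference_gene, sample) - table.mean_ct(gene, sample)
    return float(2.0 ** dct)


def fold_change_ddct(table: CtTable, gene: str, treated_sample: str,
                     control_sample: str) -> float:
    """2^-ddCt fold change of a gene in treated vs control samples."""
    dct_treated = (table.mean_ct(gene, treated_sample)
                   - table.mean_ct(table.reference_gene, treated_sample))
    dct_control = (table.mean_ct(gene, control_sample)
                   - table.mean_ct(table.reference_gene, control_sample))
    return float(2.0 ** -(dct_treated - dct_control))


def expression_matrix(table: CtTable, mode: str = "dct",
                      control_sample: str | None = None,
                      log2: bool = False) -> pd.DataFrame:
    """Genes x samples matrix of 2^dCt or 2^-ddCt values.

    ``mode="ddct"`` needs ``control_sample``; missing (gene, sample) cells
    are left as NaN, never imputed.  With ``log2=True`` the matrix is
    log2-transformed, the form heatmap tools expect.
    """
    if mode not in ("dct", "ddct"):
        raise ValueError("mode must be 'dct' or 'ddct'")
    if mode == "ddct" and control_sample is None:
        raise ValueError("ddct mode requires a control sample")
    samples = [s for s in table.samples if mode == "dct" or s != control_sample]
    out = pd.DataFrame(index=table.genes, columns=samples, dtype=float)
    for gene in table.genes:
        for sample in samples:
            try:
                if mode == "dct":
                    out.loc[gene, sample] = relative_expression_dct(table, gene, sample)
                else:
                    out.loc[gene, sample] = fold_change_ddct(
                        table, gene, sample, control_sample)
            except KeyError:
                pass  # missing cell stays NaN
    return np.log2(out) if log2 else out


# ---------------------------------------------------------------------------
# Oocyte swelling

@dataclass(frozen=True)
class SwellingSeries:
    """Cross-sectional area vs time for one oocyte.

    ``times`` in minutes (strictly increasing from 0), ``areas`` in
    length^2 units consistent with the osmolalities (cm^2 when osmolality
    is mol/cm^3), ``osm_in > osm_out`` for a hypo-osmotic swelling assay.
    """

    oocyte_id: str
    times: tuple[float, ...]
    areas: tuple[float, ...]
    osm_in: float
    osm_out: float
    group: str = "construct"

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.areas, dtype=float)
        if len(t) != len(a):
            raise ValueError("times and areas differ in length")
        if t[0] != 0 or np.any(np.diff(t) <= 0):
            raise ValueError("times must start at 0 and strictly increase")
        if np.any(a <= 0):
            raise ValueError("areas must be positive")


@dataclass(frozen=True)
class PfResult:
    """Osmotic water permeability of one oocyte with its fit inputs."""

    oocyte_id: str
    pf: float
    v0: float
    s0: float
    slope: float  # d(V/V0)/dt at t=0, per second
    vw: float = VW_WATER
    group: str = "construct"


def sphere_geometry(area: float) -> tuple[float, float]:
    """Volume and surface area of a sphere from its cross-sectional area."""
    if area <= 0:
        raise ValueError("area must be positive")
    r = sqrt(area / pi)
    return (4.0 / 3.0) * pi * r ** 3, 4.0 * pi * r ** 2


def compute_pf(series: SwellingSeries, window_minutes: float = 10.0,
               method: str = "spherical", vw: float = VW_WATER) -> PfResult:
    """Osmotic water permeability from the initial swelling rate.

    The default ``spherical`` estimator fits (V/V0)^(1/3), which the
    spherical swelling model makes exactly linear in time, so the initial
    slope d(V/V0)/dt|0 = 3 * slope of the fit is recovered without the
    curvature bias a straight-line fit of V/V0 incurs on longer windows.
    ``method="linear"`` is the literal least-squares slope of V/V0 vs t.
    """
    if series.osm_in == series.osm_out:
        raise ValueError("osmotic gradient is zero")
    t = np.asarray(series.times, dtype=float)
    a = np.asarray(series.areas, dtype=float)
    in_window = t <= window_minutes
    if in_window.sum() < 3:
        raise ValueError("need at least three time points inside the window")
    t_s = t[in_window] * 60.0
    volumes = np.array([sphere_geometry(x)[0] for x in a[in_window]])
    v0, s0 = sphere_geometry(a[0])
    rel = volumes / v0
    if method == "spherical":
        slope = 3.0 * np.polyfit(t_s, np.cbrt(rel), 1)[0]
    elif method == "linear":
        slope = np.polyfit(t_s, rel, 1)[0]
    else:
        raise ValueError("method must be 'spherical' or 'linear'")
    pf = v0 * slope / (s0 * vw * (series.osm_in - series.osm_out))
    return PfResult(oocyte_id=series.oocyte_id, pf=float(pf), v0=float(v0),
                    s0=float(s0), slope=float(slope), vw=vw, group=series.group)


@dataclass
class PfComparison:
    """Group means, fold changes vs control, one-way ANOVA and LSD tests."""

    group_means: dict[str, float]
    fold_changes: dict[str, float]
    f_statistic: float
    anova_p: float
    lsd_p: dict[tuple[str, str], float] = field(default_factory=dict)


def pf_group_comparison(results: dict[str, list[PfResult]],
                        control: str = "water") -> PfComparison:
    """Compare per-group mean Pf by one-way ANOVA with LSD pairwise tests.

    The LSD (least significant difference) test uses t statistics with the
    pooled within-group mean square from the ANOVA, the classical Fisher
    procedure.  Fold changes are group means over the control-group mean.
    """
    if len(results) < 2:
        raise ValueError("need at least two groups")
    for name, members in results.items():
        if len(members) < 2:
            raise ValueError(f"group {name!r} has fewer than two oocytes")
    if control not in results:
        raise ValueError(f"control group {control!r} missing")
    values = {name: np.array([r.pf for r in members])
              for name, members in results.items()}
    means = {name: float(v.mean()) for name, v in values.items()}
    folds = {name: means[name] / means[control] for name in values}
    f_stat, p = stats.f_oneway(*values.values())

    n_total = sum(len(v) for v in values.values())
    k = len(values)
    mse = sum(((v - v.mean()) ** 2).sum() for v in values.values()) / (n_total - k)
    lsd = {}
    for g1, g2 in itertools.combinations(sorted(values), 2):
        v1, v2 = values[g1], values[g2]
        se = sqrt(mse * (1 / len(v1) + 1 / len(v2)))
        tval = (v1.mean() - v2.mean()) / se if se > 0 else 0.0
        lsd[(g1, g2)] = float(2 * stats.t.sf(abs(tval), n_total - k))
    return PfComparison(group_means=means, fold_changes=folds,
                        f_statistic=float(f_stat), anova_p=float(p), lsd_p=lsd)
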