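"""Subsystem-level benchmarking of model predictions against omics signal.

Fluxes (or CPM) are summed by annotated subsystem, transformed as
log10(f + 1), and compared by ordinary least squares and Pearson
correlation.  Per-sample profiles can be stacked (repeated subsystem rows)
to use every sample in one regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "SubsystemProfile",
    "BenchmarkResult",
    "InsufficientDataError",
    "CoupledScenarioResult",
    "aggregate_subsystem",
    "normalize_per_million",
    "stack_profiles",
    "correlate_profiles",
    "coupled_model_omics_scenario",
]


class InsufficientDataError(ValueError):
    """Fewer than three shared subsystems between the two profiles."""


@dataclass
class SubsystemProfile:
    """Per-subsystem aggregated value f and its log10(f+1) transform."""

    table: pd.DataFrame  # index subsystem; columns f, log_f
    mode: str
    unmapped: list[str] = field(default_factory=list)


@dataclass
class BenchmarkResult:
    n: int
    slope: float
    intercept: float
    slope_ci: tuple[float, float]  # 95%
    intercept_ci: tuple[float, float]
    pcc: float
    p_value: float  # two-sided Pearson p
    regression_p: float  # slope t-test p from the OLS fit
    excluded: list[str]
    x: np.ndarray
    y: np.ndarray

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "slope": self.slope,
            "intercept": self.intercept,
            "slope_ci": list(self.slope_ci),
            "intercept_ci": list(self.intercept_ci),
            "pcc": self.pcc,
            "p_value": self.p_value,
            "regression_p": self.regression_p,
            "excluded": list(self.excluded),
        }


def aggregate_subsystem(
    values: dict[str, float],
    mapping: dict[str, str | list[str]],
    mode: str = "reaction_flux",
) -> SubsystemProfile:
    """Sum |values| by subsystem; ids serving several subsystems contribute
    to each; ids without a mapping are reported, not silently dropped."""
    if mode not in ("reaction_flux", "translation_flux", "cpm"):
        raise ValueError(f"unknown mode {mode!r}")
    if not mapping:
        raise ValueError("empty id -> subsystem mapping")
    sums: dict[str, float] = {}
    unmapped = []
    for key, value in values.items():
        subsystems = mapping.get(key)
        if subsystems is None:
            unmapped.append(key)
            continue
        if isinstance(subsystems, str):
            subsystems = [subsystems]
        for s in subsystems:
            sums[s] = sums.get(s, 0.0) + abs(float(value))
    f = pd.Series(sums, dtype=float).sort_index()
    table = pd.DataFrame({"f": f, "log_f": np.log10(f + 1.0)})
    table.index.name = "subsystem"
    return SubsystemProfile(table=table, mode=mode, unmapped=sorted(unmapped))


def normalize_per_million(profile: SubsystemProfile) -> SubsystemProfile:
    """Rescale f to parts-per-million of the profile total (log recomputed).

    Model fluxes and sequencing CPM live on incommensurable scales; for
    cross-layer correlation both are expressed as allocation shares x 1e6,
    mirroring the CPM convention, so the log10(f+1) transform acts in the
    same regime on both sides.
    """
    total = float(profile.table["f"].sum())
    if total <= 0:
        raise ValueError("profile total must be positive to normalize")
    f = profile.table["f"] * (1e6 / total)
    table = pd.DataFrame({"f": f, "log_f": np.log10(f + 1.0)})
    table.index.name = "subsystem"
    return SubsystemProfile(table=table, mode=profile.mode, unmapped=list(profile.unmapped))


def stack_profiles(profiles: list[SubsystemProfile]) -> SubsystemProfile:
    """Concatenate per-sample profiles, keeping repeated subsystem rows, so a
    downstream regression uses every sample (maximal statistical power)."""
    if not profiles:
        raise ValueError("no profiles to stack")
    table = pd.concat([p.table for p in profiles], axis=0)
    unmapped = sorted({u for p in profiles for u in p.unmapped})
    return SubsystemProfile(table=table, mode=profiles[0].mode, unmapped=unmapped)


def correlate_profiles(x: SubsystemProfile, y: SubsystemProfile) -> BenchmarkResult:
    """OLS of y on x and Pearson correlation, on the log10(f+1) scale.

    Profiles are aligned on subsystem labels (respecting multiplicity for
    stacked profiles); subsystems absent from either side are excluded and
    reported.  Regression of y on x is directional; the PCC is symmetric.
    """
    xt, yt = x.table, y.table
    shared = sorted(set(xt.index) & set(yt.index))
    excluded = sorted(set(xt.index) ^ set(yt.index))
    xs, ys = [], []
    for s in shared:
        xv = np.atleast_1d(xt.loc[s, "log_f"])
        yv = np.atleast_1d(yt.loc[s, "log_f"])
        k = min(len(xv), len(yv))  # pair repeated rows positionally
        xs.extend(xv[:k])
        ys.extend(yv[:k])
    xv = np.asarray(xs, dtype=float)
    yv = np.asarray(ys, dtype=float)
    if len(set(shared)) < 3:
        raise InsufficientDataError(
            f"need >= 3 shared subsystems, got {len(set(shared))}"
        )
    X = sm.add_constant(xv)
    fit = sm.OLS(yv, X).fit()
    if fit.params.shape[0] < 2:  # constant x collapses the design matrix
        raise InsufficientDataError("profile x is constant; regression undefined")
    ci = fit.conf_int(alpha=0.05)
    pear = stats.pearsonr(xv, yv)
    return BenchmarkResult(
        n=len(xv),
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        slope_ci=(float(ci[1, 0]), float(ci[1, 1])),
        intercept_ci=(float(ci[0, 0]), float(ci[0, 1])),
        pcc=float(pear.statistic),
        p_value=float(pear.pvalue),
        regression_p=float(fit.pvalues[1]),
        excluded=excluded,
        x=xv,
        y=yv,
    )


# ---------------------------------------------------------------------------
# Coupled model <-> omics scenario


@dataclass
class CoupledScenarioResult:
    me_vs_ribo: BenchmarkResult
    m_vs_ribo: BenchmarkResult
    mu_me: float
    mu_m: float

    def to_dict(self) -> dict:
        return {
            "me_vs_ribo": self.me_vs_ribo.to_dict(),
            "m_vs_ribo": self.m_vs_ribo.to_dict(),
            "mu_me": self.mu_me,
            "mu_m": self.mu_m,
        }


def coupled_model_omics_scenario(
    seed: int,
    n_accessory: int = 30,
    noise_sdlog: float = 0.3,
    depth: float = 5e6,
    n_replicates: int = 3,
) -> CoupledScenarioResult:
    """Simulate Ribo-Seq whose gene abundances track the ME model's
    proteome allocation, then benchmark both models against it.

    A toy cell with ``n_accessory`` accessory pathways is solved at maximum
    growth.  Ribosome-footprint abundance per gene is its ME translation flux
    times log-normal noise; counts are drawn with the standard simulator.
    Ribo CPM, ME translation fluxes, and metabolism-only reaction fluxes are
    each summed by subsystem and correlated on the log10(f+1) scale.  The
    expression layer ties flux to enzyme demand through keff, which the
    metabolism-only analog cannot see — so its profile should correlate
    less well with the simulated footprints.
    """
    from . import me_core
    from .synthetic_data import OmicsDesign, make_benchmark_cell

    me, m_analog = make_benchmark_cell(seed, n_accessory=n_accessory)
    sol_me = me_core.maximize_growth(me)
    sol_m = me_core.maximize_growth(m_analog)

    genes = [g for g in me.genes]
    tl_flux = {g: sol_me.fluxes[me.translation_of[g]] for g in genes}
    subsystem_of_gene = {}
    for g in genes:
        home = me_core.catalyzed_reaction_of(me, g)
        if home is not None:
            subsystem_of_gene[g] = me.subsystem_of[home]

    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(17,)))
    design_ids = [f"g{i:04d}" for i in range(len(genes))]
    alias = dict(zip(design_ids, genes))
    abundances = {
        did: tl_flux[alias[did]] * float(rng.lognormal(0.0, noise_sdlog))
        for did in design_ids
    }
    design = OmicsDesign(
        n_genes=len(genes),
        n_replicates=n_replicates,
        depth=depth,
        abundances=abundances,
        seed=int(np.random.SeedSequence(seed, spawn_key=(18,)).generate_state(1)[0] % 2**31),
    )
    from .omics import cpm_normalize
    from .synthetic_data import simulate_counts

    _, ribo, _ = simulate_counts(design)
    ribo_cpm = cpm_normalize(ribo)
    mean_cpm = {alias[did]: float(v) for did, v in ribo_cpm.values.mean(axis=1).items()}

    cpm_profile = normalize_per_million(
        aggregate_subsystem(mean_cpm, subsystem_of_gene, "cpm")
    )
    me_profile = normalize_per_million(
        aggregate_subsystem(tl_flux, subsystem_of_gene, "translation_flux")
    )
    m_profile = normalize_per_million(
        aggregate_subsystem(sol_m.fluxes, m_analog.subsystem_of, "reaction_flux")
    )
    return CoupledScenarioResult(
        me_vs_ribo=correlate_profiles(me_profile, cpm_profile),
        m_vs_ribo=correlate_profiles(m_profile, cpm_profile),
        mu_me=sol_me.mu_star,
        mu_m=sol_m.mu_star,
    )
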