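"""Synthetic study systems with known ground truth.

Two generators live here:

* :func:`make_minicell` builds a paired toy ME model / metabolism-only analog
  engineered to display proteome limitation and overflow metabolism: a
  high-yield but proteome-expensive respiration branch competes with a
  low-yield, proteome-cheap overflow branch that secretes a by-product.  At
  low substrate uptake the high-yield branch wins; once growth is fast enough
  that enzyme expression dominates the budget, flux shifts to the cheap
  branch and the by-product is secreted — the classic overflow switch.

* :func:`simulate_counts` draws paired RNA-Seq / Ribo-Seq negative-binomial
  count tables with planted pathway-level translational-efficiency (TE)
  effects and returns the generating truth for recovery tests.

Both are fully deterministic given their parameter object (which carries the
seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .me_core import MEModel, Reaction, strip_expression

__all__ = [
    "MinicellParams",
    "OmicsDesign",
    "OmicsTruth",
    "CountMatrix",
    "GenerationError",
    "make_minicell",
    "make_benchmark_cell",
    "random_minicell_params",
    "simulate_counts",
    "default_omics_design",
]


class GenerationError(ValueError):
    """Generator parameters cannot produce a valid study system."""


# ---------------------------------------------------------------------------
# Toy ME models


@dataclass
class MinicellParams:
    """Parameters of the toy cell.

    Yields are biomass per substrate (gDW/mmol-equivalents); ``keff`` are
    effective catalytic rates (1/h); protein lengths in amino acids; the
    ribosome elongation capacity in aa/(h.ribosome).  The invariant that
    makes overflow possible: respiration has the higher yield but the higher
    proteome cost (length/keff), while the overflow branch alone supports a
    higher growth ceiling.
    """

    yield_respiration: float = 0.10
    yield_overflow: float = 0.05
    keff: dict[str, float] = field(
        default_factory=lambda: {
            "respiration_a": 20.0,
            "respiration_b": 6.0,
            "overflow": 12.0,
        }
    )
    protein_length: dict[str, float] = field(
        default_factory=lambda: {
            "respiration_a": 400.0,
            "respiration_b": 400.0,
            "overflow": 160.0,
            "ribosome": 7500.0,
        }
    )
    ribosome_capacity: float = 60000.0  # aa/(h.ribosome)
    #: cap (model flux units) on translation of the primary respiratory
    #: enzyme — a coarse stand-in for the membrane real estate available to
    #: the respiratory chain.  Protein balance turns it into a growth-rate-
    #: dependent respiration capacity keff * cap / mu, so overflow starts
    #: gradually once growth is fast enough; the cap lives on an expression
    #: reaction and therefore vanishes in the stripped metabolism-only analog.
    respiration_translation_cap: float | None = 0.075
    biomass_per_aa: float = 0.01  # biomass precursor units per aa polymerized
    nt_cost: float = 0.0005  # biomass precursor units per nt transcribed
    k_mrna: float = 200.0  # protein/(mRNA.h): translation flux per mRNA
    uptake_exchange_id: str = "EX_substrate"
    reference_uptake: float = 10.0  # mmol/gDW/h
    include_overflow: bool = True
    mu_max_hint: float = 5.0
    seed: int = 0

    def proteome_cost(self, enzyme: str) -> float:
        """length/keff — proteome time-cost per unit of catalyzed flux."""
        return self.protein_length[enzyme] / self.keff[enzyme]

    def validate(self) -> None:
        if self.yield_respiration <= 0 or self.yield_overflow <= 0:
            raise GenerationError("yields must be > 0")
        if any(k <= 0 for k in self.keff.values()):
            raise GenerationError("keff values must be > 0")
        if any(l <= 0 for l in self.protein_length.values()):
            raise GenerationError("protein lengths must be > 0")
        if self.include_overflow:
            if self.yield_respiration <= self.yield_overflow:
                raise GenerationError(
                    "respiration must have the higher yield than overflow"
                )
            if self.proteome_cost("respiration_a") <= self.proteome_cost("overflow"):
                raise GenerationError(
                    "respiration must have the higher proteome cost "
                    "(length/keff) than overflow"
                )


#: enzyme -> (gene, metabolic reaction id, subsystem)
_ENZYMES = {
    "respiration_a": ("g_resp_a", "RESP_A", "respiration"),
    "respiration_b": ("g_resp_b", "RESP_B", "respiration"),
    "overflow": ("g_ovf", "OVF", "overflow"),
}

_BIG = 1000.0


def _expression_reactions(
    enzyme: str,
    gene: str,
    params: MinicellParams,
    product_metabolite: str,
) -> tuple[list[str], list[Reaction], str]:
    """mRNA species + transcription and translation reactions for one gene.

    Translation couples ribosome usage (mu * L / capacity) and mRNA usage
    (mu / k_mrna); the enzyme itself is consumed by its metabolic reaction at
    mu / keff, which is its dilution term.
    """
    L = params.protein_length[enzyme]
    mrna = f"mRNA_{gene}"
    tl_id = f"TL_{gene}"
    tx = Reaction(
        id=f"TX_{gene}",
        lower_bound=0.0,
        upper_bound=_BIG,
        entries=[("biomass_precursor", -3.0 * L * params.nt_cost, 0.0), (mrna, 1.0, 0.0)],
        subsystem="transcription",
    )
    tl = Reaction(
        id=tl_id,
        lower_bound=0.0,
        upper_bound=_BIG,
        entries=[
            ("biomass_precursor", -L * params.biomass_per_aa, 0.0),
            (product_metabolite, 1.0, 0.0),
            ("ribosome", 0.0, -L / params.ribosome_capacity),
            (mrna, 0.0, -1.0 / params.k_mrna),
        ],
        subsystem="translation",
    )
    return [mrna], [tx, tl], tl_id


def make_minicell(params: MinicellParams | None = None) -> tuple[MEModel, MEModel]:
    """Build the toy ME model and its stripped metabolism-only analog."""
    params = params or MinicellParams()
    params.validate()

    enzymes = dict(_ENZYMES)
    if not params.include_overflow:
        enzymes.pop("overflow")

    metabolites = ["substrate", "biomass_precursor", "ribosome"]
    reactions: list[Reaction] = [
        Reaction(
            id=params.uptake_exchange_id,
            lower_bound=-params.reference_uptake,
            upper_bound=0.0,
            entries=[("substrate", -1.0, 0.0)],
            subsystem="exchange",
        ),
        Reaction(
            id="BIOMASS",
            lower_bound=0.0,
            upper_bound=_BIG,
            entries=[("biomass_precursor", -1.0, 0.0)],
            subsystem="biomass",
        ),
    ]
    if params.include_overflow:
        metabolites.append("overflow_product")
        reactions.append(
            Reaction(
                id="EX_overflow",
                lower_bound=0.0,
                upper_bound=_BIG,
                entries=[("overflow_product", -1.0, 0.0)],
                subsystem="exchange",
            )
        )

    genes: list[str] = []
    translation_of: dict[str, str] = {}

    # ribosome: translated by its own gene, using itself
    rib_gene = "g_ribosome"
    rib_L = params.protein_length["ribosome"]
    mrna_rib = f"mRNA_{rib_gene}"
    metabolites.append(mrna_rib)
    reactions.append(
        Reaction(
            id=f"TX_{rib_gene}",
            lower_bound=0.0,
            upper_bound=_BIG,
            entries=[
                ("biomass_precursor", -3.0 * rib_L * params.nt_cost, 0.0),
                (mrna_rib, 1.0, 0.0),
            ],
            subsystem="transcription",
        )
    )
    reactions.append(
        Reaction(
            id=f"TL_{rib_gene}",
            lower_bound=0.0,
            upper_bound=_BIG,
            entries=[
                ("biomass_precursor", -rib_L * params.biomass_per_aa, 0.0),
                ("ribosome", 1.0, -rib_L / params.ribosome_capacity),
                (mrna_rib, 0.0, -1.0 / params.k_mrna),
            ],
            subsystem="translation",
        )
    )
    genes.append(rib_gene)
    translation_of[rib_gene] = f"TL_{rib_gene}"

    for enzyme, (gene, rxn_id, subsystem) in enzymes.items():
        protein = f"protein_{gene}"
        metabolites.append(protein)
        yld = (
            params.yield_respiration
            if enzyme.startswith("respiration")
            else params.yield_overflow
        )
        entries = [
            ("substrate", -1.0, 0.0),
            ("biomass_precursor", yld, 0.0),
            # enzyme usage + dilution: mu/keff per unit flux
            (protein, 0.0, -1.0 / params.keff[enzyme]),
        ]
        if enzyme == "overflow":
            entries.append(("overflow_product", 1.0, 0.0))
        reactions.append(
            Reaction(
                id=rxn_id,
                lower_bound=0.0,
                upper_bound=_BIG,
                entries=entries,
                subsystem=subsystem,
            )
        )
        new_mets, expr_rxns, tl_id = _expression_reactions(enzyme, gene, params, protein)
        metabolites.extend(new_mets)
        reactions.extend(expr_rxns)
        genes.append(gene)
        translation_of[gene] = tl_id

    if params.respiration_translation_cap is not None:
        for rxn in reactions:
            if rxn.id == "TL_g_resp_a":
                rxn.upper_bound = params.respiration_translation_cap

    me = MEModel(
        metabolite_ids=metabolites,
        reactions=reactions,
        genes=genes,
        translation_of=translation_of,
        growth_reaction_id="BIOMASS",
        mu_max_hint=params.mu_max_hint,
    )
    m_analog = strip_expression(me)
    return me, m_analog


def random_minicell_params(seed: int) -> MinicellParams:
    """A seeded variant of the default toy cell: yields, catalytic rates and
    protein lengths jittered +-20% while preserving the overflow-enabling
    orderings (regenerated until the invariant holds)."""
    rng = np.random.default_rng(seed)
    for _ in range(100):
        jit = lambda x: float(x * rng.uniform(0.8, 1.2))  # noqa: E731
        p = MinicellParams(
            yield_respiration=jit(0.10),
            yield_overflow=jit(0.05),
            keff={
                "respiration_a": jit(20.0),
                "respiration_b": jit(6.0),
                "overflow": jit(12.0),
            },
            protein_length={
                "respiration_a": jit(400.0),
                "respiration_b": jit(400.0),
                "overflow": jit(160.0),
                "ribosome": jit(7500.0),
            },
            ribosome_capacity=jit(60000.0),
            respiration_translation_cap=jit(0.075),
            seed=seed,
        )
        try:
            p.validate()
        except GenerationError:
            continue
        return p
    raise GenerationError(f"no valid parameter draw for seed {seed}")  # pragma: no cover


def make_benchmark_cell(
    seed: int,
    n_accessory: int = 30,
    demand_meanlog: float = -2.5,
    demand_sdlog: float = 1.0,
    keff_meanlog: float = 3.0,
    keff_sdlog: float = 0.8,
) -> tuple[MEModel, MEModel]:
    """Minicell extended with accessory pathways for model-vs-omics studies.

    Each accessory pathway converts substrate into a secreted product at a
    small fixed demand, catalyzed by its own enzyme (own gene, own subsystem).
    The ME translation flux of pathway ``i`` is ``mu * demand_i / keff_i`` —
    proteome allocation shaped by both demand and catalytic efficiency —
    whereas the metabolism-only analog sees only the demand flux itself.
    """
    params = MinicellParams(seed=seed)
    rng = np.random.default_rng(seed)
    me, _ = make_minicell(params)
    metabolites = list(me.metabolite_ids)
    reactions = list(me.reactions)
    genes = list(me.genes)
    translation_of = dict(me.translation_of)
    for i in range(n_accessory):
        gene = f"g_acc{i:03d}"
        product = f"acc_product_{i:03d}"
        demand = float(rng.lognormal(demand_meanlog, demand_sdlog))
        keff = float(rng.lognormal(keff_meanlog, keff_sdlog))
        length = float(rng.uniform(100, 600))
        protein = f"protein_{gene}"
        metabolites += [product, protein]
        reactions.append(
            Reaction(
                id=f"ACC_{i:03d}",
                lower_bound=demand,
                upper_bound=demand,
                entries=[
                    ("substrate", -1.0, 0.0),
                    (product, 1.0, 0.0),
                    (protein, 0.0, -1.0 / keff),
                ],
                subsystem=f"accessory_{i:03d}",
            )
        )
        reactions.append(
            Reaction(
                id=f"EX_acc_{i:03d}",
                lower_bound=0.0,
                upper_bound=_BIG,
                entries=[(product, -1.0, 0.0)],
                subsystem="exchange",
            )
        )
        aux = MinicellParams(seed=seed)
        aux.protein_length[gene] = length
        aux.keff[gene] = keff
        new_mets, expr_rxns, tl_id = _expression_reactions(gene, gene, aux, protein)
        metabolites.extend(new_mets)
        reactions.extend(expr_rxns)
        genes.append(gene)
        translation_of[gene] = tl_id
    me_ext = MEModel(
        metabolite_ids=metabolites,
        reactions=reactions,
        genes=genes,
        translation_of=translation_of,
        growth_reaction_id="BIOMASS",
        mu_max_hint=params.mu_max_hint,
    )
    return me_ext, strip_expression(me_ext)


# ---------------------------------------------------------------------------
# Paired RNA-Seq / Ribo-Seq counts


@dataclass
class CountMatrix:
    """Gene x sample nonnegative integer counts for one assay."""

    counts: pd.DataFrame  # index gene, columns sample ids like "rna_1"
    assay_of: dict[str, str]  # sample -> "rna" | "ribo"
    replicate_of: dict[str, int]

    def __post_init__(self) -> None:
        c = self.counts
        c.index.name = "gene"
        if (c.to_numpy() < 0).any():
            raise ValueError("negative counts")
        totals = c.sum(axis=0)
        if (totals <= 0).any():
            bad = list(totals[totals <= 0].index)
            raise ValueError(f"samples with zero total counts: {bad}")
        missing = set(c.columns) - set(self.assay_of) | set(c.columns) - set(
            self.replicate_of
        )
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class OmicsDesign:
    """Generative design for paired RNA/Ribo counts.

    Gene baseline abundances follow a hierarchical log-normal: each pathway
    draws a pathway-level log-abundance (sdlog ``between_sdlog``) shared by
    its genes — emulating operon-level co-regulation in bacteria — and each
    gene adds residual noise (``within_sdlog``).  The combined spread puts
    several orders of magnitude between the least and most expressed genes.
    TE is multiplicative: the pathway's planted effect times gene-level
    log-normal noise.
    """

    n_genes: int = 1000
    pathways: dict[str, list[str]] = field(default_factory=dict)
    n_replicates: int = 3
    depth: float = 5e6
    baseline_meanlog: float = 0.0
    between_sdlog: float = 1.8
    within_sdlog: float = 0.5
    dispersion: float = 0.05  # NB: var = m + dispersion * m^2
    te_effects: dict[str, float] = field(default_factory=dict)
    te_noise_sdlog: float = 0.1
    depth_factor_sdlog: float = 0.1
    abundances: dict[str, float] | None = None  # optional explicit baseline
    seed: int = 0

    def gene_ids(self) -> list[str]:
        return [f"g{i:04d}" for i in range(self.n_genes)]

    def validate(self) -> None:
        if self.n_replicates < 2:
            raise GenerationError("need at least 2 replicates")
        if self.depth <= 0:
            raise GenerationError("depth must be > 0")
        if any(e <= 0 for e in self.te_effects.values()):
            raise GenerationError("te_effects must be > 0")
        if set(self.te_effects) - set(self.pathways):
            raise GenerationError("te_effects reference unknown pathways")
        universe = set(self.gene_ids())
        for pw, gs in self.pathways.items():
            unknown = set(gs) - universe
            if unknown:
                raise GenerationError(
                    f"pathway {pw!r} references unknown genes: {sorted(unknown)[:5]}"
                )


@dataclass
class OmicsTruth:
    """Generating truth stored alongside every simulated dataset."""

    abundance: dict[str, float]  # relative mRNA abundance (sums to 1)
    te: dict[str, float]  # per-gene translational efficiency
    pathway_te_effect: dict[str, float]
    expected_class: dict[str, str]  # pathway -> up | down | ns
    depth_factors: dict[str, float]  # per sample

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)


def default_omics_design(
    seed: int = 0,
    n_genes: int = 1000,
    n_pathways: int = 50,
    genes_per_pathway: int = 10,
    te_effects: dict[str, float] | None = None,
    **kwargs,
) -> OmicsDesign:
    """Design with ``n_pathways`` disjoint pathways over the leading genes."""
    gene_ids = [f"g{i:04d}" for i in range(n_genes)]
    pathways = {
        f"pw{p:03d}": gene_ids[p * genes_per_pathway : (p + 1) * genes_per_pathway]
        for p in range(n_pathways)
    }
    if n_pathways * genes_per_pathway > n_genes:
        raise GenerationError("pathways exceed the gene universe")
    return OmicsDesign(
        n_genes=n_genes,
        pathways=pathways,
        te_effects=dict(te_effects or {}),
        seed=seed,
        **kwargs,
    )


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with mean m and var m + dispersion m^2 (Poisson at 0)."""
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_counts(design: OmicsDesign) -> tuple[CountMatrix, CountMatrix, OmicsTruth]:
    """Draw paired RNA-Seq / Ribo-Seq count matrices plus generating truth."""
    design.validate()
    rng = np.random.default_rng(design.seed)
    genes = design.gene_ids()
    n = len(genes)

    pathway_of: dict[str, str] = {}
    for pw, gs in design.pathways.items():
        for g in gs:
            pathway_of.setdefault(g, pw)

    # latent baseline abundances (relative, sum to 1)
    if design.abundances is not None:
        ab = np.array([design.abundances.get(g, 0.0) for g in genes], dtype=float)
        if (ab < 0).any() or ab.sum() <= 0:
            raise GenerationError("explicit abundances must be nonnegative, sum > 0")
    else:
        pathway_level = {
            pw: rng.normal(design.baseline_meanlog, design.between_sdlog)
            for pw in design.pathways
        }
        log_ab = np.empty(n)
        for i, g in enumerate(genes):
            base = pathway_level.get(
                pathway_of.get(g, ""),
                rng.normal(design.baseline_meanlog, design.between_sdlog),
            )
            log_ab[i] = base + rng.normal(0.0, design.within_sdlog)
        ab = np.exp(log_ab)
    ab = ab / ab.sum()

    te_gene = np.array(
        [design.te_effects.get(pathway_of.get(g, ""), 1.0) for g in genes]
    )
    if design.te_noise_sdlog > 0:
        te_gene = te_gene * rng.lognormal(0.0, design.te_noise_sdlog, size=n)

    def draw_assay(mean_rel: np.ndarray, prefix: str) -> tuple[pd.DataFrame, dict]:
        cols, factors = {}, {}
        for rep in range(1, design.n_replicates + 1):
            f = float(rng.lognormal(0.0, design.depth_factor_sdlog))
            mean = mean_rel * design.depth * f
            cols[f"{prefix}_{rep}"] = _nb_draw(rng, mean, design.dispersion)
            factors[f"{prefix}_{rep}"] = f
        return pd.DataFrame(cols, index=genes), factors

    rna_df, rna_f = draw_assay(ab, "rna")
    ribo_df, ribo_f = draw_assay(ab * te_gene, "ribo")

    def meta(df: pd.DataFrame, assay: str) -> CountMatrix:
        return CountMatrix(
            counts=df,
            assay_of={c: assay for c in df.columns},
            replicate_of={c: int(c.split("_")[1]) for c in df.columns},
        )

    expected = {}
    for pw in design.pathways:
        eff = design.te_effects.get(pw, 1.0)
        expected[pw] = "up" if eff > 1.0 else ("down" if eff < 1.0 else "ns")
    truth = OmicsTruth(
        abundance=dict(zip(genes, map(float, ab))),
        te=dict(zip(genes, map(float, te_gene))),
        pathway_te_effect={pw: design.te_effects.get(pw, 1.0) for pw in design.pathways},
        expected_class=expected,
        depth_factors={**rna_f, **ribo_f},
    )
    return meta(rna_df, "rna"), meta(ribo_df, "ribo"), truth
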