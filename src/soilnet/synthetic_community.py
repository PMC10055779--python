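"""Synthetic soil-community generator.

Emulates the study design every downstream stage expects: 18 treatment cells
(3 biomass levels x 3 fertilizers x 2 habitats) plus native soil, 3
replicates each (57 samples).  Counts follow a latent-factor log-normal ->
Dirichlet-multinomial model: planted association blocks share latent Gaussian
factors (copula-style, inducing rank correlation that survives the count
layer), per-cell target compositions set the mean relative abundances, and an
overdispersed multinomial draws the reads.  Ground truth (planted edges,
planted factor effects, expected compositions) is returned for recovery
checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_tables import (
    FERTILIZERS,
    HABITATS,
    ISMB_LEVELS,
    NATIVE,
    CountTable,
    SampleDesign,
    SampleInfo,
    TaxonomyMap,
    parse_lineage,
)

__all__ = [
    "TaxonSpec",
    "AssociationBlock",
    "CovariateSpec",
    "SimulationConfig",
    "GroundTruth",
    "cell_codes",
    "generate_dataset",
    "default_paper_profile",
    "null_profile",
]

DEFAULT_SEED = 20170001


@dataclass(frozen=True)
class TaxonSpec:
    name: str
    kingdom: str  # "bacteria" or "fungi"
    lineage: str


@dataclass(frozen=True)
class AssociationBlock:
    """Taxa sharing a latent Gaussian factor.

    ``sign`` +1 loads every member positively; -1 alternates member loadings
    so consecutive members anti-correlate.
    """

    taxa: tuple[str, ...]
    loading: float
    sign: int = 1

    def member_loadings(self) -> dict[str, float]:
        out = {}
        for idx, taxon in enumerate(self.taxa):
            flip = -1.0 if (self.sign < 0 and idx % 2 == 1) else 1.0
            out[taxon] = flip * self.loading
        return out

    def planted_edges(self) -> list[tuple[str, str, int]]:
        loads = self.member_loadings()
        edges = []
        for i in range(len(self.taxa)):
            for j in range(i + 1, len(self.taxa)):
                a, b = self.taxa[i], self.taxa[j]
                edges.append((a, b, 1 if loads[a] * loads[b] > 0 else -1))
        return edges


@dataclass(frozen=True)
class CovariateSpec:
    name: str
    base: float
    noise_sd: float = 0.0
    ismb_effect: dict = field(default_factory=dict)        # level -> delta
    fertilizer_effect: dict = field(default_factory=dict)  # type -> delta
    habitat_effect: dict = field(default_factory=dict)     # habitat -> delta
    interaction: dict = field(default_factory=dict)        # (fert, ismb) -> delta
    native_value: float | None = None
    linked_taxon: str | None = None
    slope: float = 0.0


def cell_codes() -> list[str]:
    codes = [
        f"{fert}{level}_{hab}"
        for fert in FERTILIZERS
        for level in ISMB_LEVELS
        for hab in HABITATS
    ]
    codes.append(NATIVE)
    return codes


@dataclass
class SimulationConfig:
    taxa: list[TaxonSpec]
    cell_shares: dict[str, dict[str, float]]  # cell -> taxon -> within-kingdom share
    blocks: list[AssociationBlock] = field(default_factory=list)
    covariates: list[CovariateSpec] = field(default_factory=list)
    replicates: int = 3
    library_size_mean: float = 10_000.0
    library_size_cv: float = 0.1
    overdispersion: float = 0.005
    noise_sd: float = 0.35
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if not self.taxa:
            raise ValueError("config has zero taxa")
        if self.replicates < 1:
            raise ValueError("config has zero replicates")
        if self.library_size_mean < 10:
            raise ValueError("library size mean too small")
        if not 0 < self.overdispersion < 1:
            raise ValueError("overdispersion must lie in (0, 1)")
        names = [t.name for t in self.taxa]
        if len(set(names)) != len(names):
            raise ValueError("duplicate taxon names")
        name_set = set(names)
        for block in self.blocks:
            if len(set(block.taxa)) != len(block.taxa) or len(block.taxa) < 2:
                raise ValueError(f"bad association block {block.taxa}")
            unknown = set(block.taxa) - name_set
            if unknown:
                raise ValueError(f"association block references unknown taxa {unknown}")
            if not np.isfinite(block.loading):
                raise ValueError("block loading must be finite")
        expected_cells = set(cell_codes())
        if set(self.cell_shares) != expected_cells:
            raise ValueError("cell_shares must cover all 18 treatment cells plus native")
        for cell, shares in self.cell_shares.items():
            if set(shares) != name_set:
                raise ValueError(f"cell {cell}: shares must cover every taxon")
            for kingdom in self.kingdoms():
                total = sum(shares[t.name] for t in self.taxa if t.kingdom == kingdom)
                if total > 1 + 1e-9:
                    raise ValueError(f"cell {cell}: {kingdom} shares sum to {total} > 1")
                if total <= 0:
                    raise ValueError(f"cell {cell}: {kingdom} shares sum to zero")

    def kingdoms(self) -> list[str]:
        seen: list[str] = []
        for taxon in self.taxa:
            if taxon.kingdom not in seen:
                seen.append(taxon.kingdom)
        return seen

    def kingdom_taxa(self, kingdom: str) -> list[TaxonSpec]:
        return [t for t in self.taxa if t.kingdom == kingdom]


@dataclass
class GroundTruth:
    planted_edges: list[tuple[str, str, int]]
    factor_effects: dict[str, dict[str, float]]  # factor -> taxon -> max fold change
    expected_cell_shares: dict[str, dict[str, float]]

    def __post_init__(self) -> None:
        for a, b, sign in self.planted_edges:
            if a == b:
                raise ValueError("planted self-edge")
            if sign not in (-1, 1):
                raise ValueError("planted edge sign must be +1 or -1")

    def edges_for(self, taxa) -> list[tuple[str, str, int]]:
        keep = set(taxa)
        return [(a, b, s) for a, b, s in self.planted_edges if a in keep and b in keep]

    def design_driven_pairs(self) -> set[frozenset]:
        """Unordered pairs whose members both respond to the same factor.

        Such pairs genuinely co-vary across samples (including via
        compositional closure), so edge-recovery scoring treats them as
        neither true nor false positives.
        """
        out: set[frozenset] = set()
        for affected in self.factor_effects.values():
            taxa = list(affected)
            for i in range(len(taxa)):
                for j in range(i + 1, len(taxa)):
                    out.add(frozenset((taxa[i], taxa[j])))
        return out


def _cell_factors(cell: str) -> tuple[str, str, str]:
    if cell == NATIVE:
        return NATIVE, NATIVE, NATIVE
    treatment, habitat = cell.split("_")
    return treatment[1], treatment[0], habitat  # ismb, fertilizer, habitat


def _factor_effect_map(config: SimulationConfig) -> dict[str, dict[str, float]]:
    """Max fold-change of a taxon's mean share across the levels of each factor
    (averaged over the other factors); >1.5-fold counts as a planted effect."""
    out: dict[str, dict[str, float]] = {}
    cells = [c for c in cell_codes() if c != NATIVE]
    for factor, levels in (("ismb", ISMB_LEVELS), ("fertilizer", FERTILIZERS),
                           ("habitat", HABITATS)):
        effects: dict[str, float] = {}
        for spec in config.taxa:
            means = []
            for level in levels:
                vals = [
                    config.cell_shares[c][spec.name]
                    for c in cells
                    if _cell_factors(c)[("ismb", "fertilizer", "habitat").index(factor)] == level
                ]
                means.append(float(np.mean(vals)))
            low = max(min(means), 1e-12)
            fold = max(means) / low
            if fold > 1.5:
                effects[spec.name] = fold
        out[factor] = effects
    return out


_CALIBRATION_SEED = 987_654_321
_CALIBRATION_DRAWS = 2048
_CALIBRATION_ITERS = 8


def _calibrate_log_means(target: np.ndarray, lam: np.ndarray,
                         noise_sd: float) -> np.ndarray:
    """Adjust log-means so that E[softmax(log_mu + noise)] hits ``target``.

    The normalization step of the composition model (softmax over log-normal
    weights) biases expected shares toward uniformity; a fixed-point
    iteration with common random numbers removes the bias deterministically.
    """
    cal_rng = np.random.default_rng(_CALIBRATION_SEED)
    m, n = _CALIBRATION_DRAWS, len(target)
    shift = cal_rng.standard_normal((m, lam.shape[1])) @ lam.T if lam.size else 0.0
    shift = shift + cal_rng.normal(0.0, noise_sd, size=(m, n))
    log_target = np.log(np.clip(target, 1e-12, None))
    mu = log_target.copy()
    for _ in range(_CALIBRATION_ITERS):
        w = np.exp(mu + shift)
        p = w / w.sum(axis=1, keepdims=True)
        mu = mu + log_target - np.log(p.mean(axis=0))
        mu -= mu.mean()
    return mu


def generate_dataset(config: SimulationConfig, seed: int | None = None):
    """Draw a (CountTable, TaxonomyMap, SampleDesign, GroundTruth) tuple.

    Identical config and seed produce byte-identical output.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    kingdoms = config.kingdoms()
    taxa_by_kingdom = {k: config.kingdom_taxa(k) for k in kingdoms}
    loadings: dict[str, list[tuple[int, float]]] = {t.name: [] for t in config.taxa}
    for b_idx, block in enumerate(config.blocks):
        for taxon, lam in block.member_loadings().items():
            loadings[taxon].append((b_idx, lam))

    samples: list[str] = []
    infos: list[SampleInfo] = []
    columns: list[np.ndarray] = []
    all_names = [t.name for t in config.taxa]
    name_pos = {n: i for i, n in enumerate(all_names)}
    log_rel_by_sample: list[np.ndarray] = []

    lam_by_kingdom = {}
    for kingdom in kingdoms:
        names = [t.name for t in taxa_by_kingdom[kingdom]]
        lam = np.zeros((len(names), len(config.blocks)))
        for row, name in enumerate(names):
            for b_idx, loading in loadings[name]:
                lam[row, b_idx] = loading
        lam_by_kingdom[kingdom] = lam
    calibrated: dict[tuple[str, str], np.ndarray] = {}

    for cell in cell_codes():
        ismb, fert, habitat = _cell_factors(cell)
        shares = config.cell_shares[cell]
        for rep in range(1, config.replicates + 1):
            sample = f"{cell}_{rep}" if cell != NATIVE else f"native_{rep}"
            z = rng.standard_normal(len(config.blocks)) if config.blocks else np.empty(0)
            column = np.zeros(len(all_names), dtype=np.int64)
            log_rel = np.full(len(all_names), np.nan)
            for kingdom in kingdoms:
                specs = taxa_by_kingdom[kingdom]
                names = [t.name for t in specs]
                target = np.array([shares[n] for n in names], dtype=float)
                target = target / target.sum()
                key = (cell, kingdom)
                if key not in calibrated:
                    calibrated[key] = _calibrate_log_means(
                        target, lam_by_kingdom[kingdom], config.noise_sd)
                log_mu = calibrated[key]
                shift = np.array(
                    [sum(lam * z[b] for b, lam in loadings[n]) for n in names]
                )
                eps = rng.normal(0.0, config.noise_sd, size=len(names))
                weights = np.exp(log_mu + shift + eps)
                p = weights / weights.sum()
                alpha = p / config.overdispersion
                p_dm = rng.dirichlet(alpha)
                cv = config.library_size_cv
                if cv > 0:
                    lib = rng.gamma(1.0 / cv ** 2, config.library_size_mean * cv ** 2)
                else:
                    lib = config.library_size_mean
                lib = max(50, int(round(lib)))
                counts = rng.multinomial(lib, p_dm)
                for name, c, pr in zip(names, counts, p):
                    column[name_pos[name]] = c
                    log_rel[name_pos[name]] = np.log(max(pr, 1e-12))
            covs: dict[str, float] = {}
            for spec in config.covariates:
                if cell == NATIVE:
                    value = spec.native_value if spec.native_value is not None else spec.base
                else:
                    value = (
                        spec.base
                        + spec.ismb_effect.get(ismb, 0.0)
                        + spec.fertilizer_effect.get(fert, 0.0)
                        + spec.habitat_effect.get(habitat, 0.0)
                        + spec.interaction.get((fert, ismb), 0.0)
                    )
                if spec.linked_taxon is not None:
                    value += spec.slope * log_rel[name_pos[spec.linked_taxon]]
                if spec.noise_sd > 0:
                    value += rng.normal(0.0, spec.noise_sd)
                covs[spec.name] = float(value)
            samples.append(sample)
            infos.append(SampleInfo(sample, ismb, fert, habitat, rep, covs))
            columns.append(column)
            log_rel_by_sample.append(log_rel)

    table = CountTable(all_names, samples, np.column_stack(columns))
    taxonomy = TaxonomyMap({t.name: parse_lineage(t.lineage) for t in config.taxa})
    design = SampleDesign(infos)
    truth = GroundTruth(
        planted_edges=[e for block in config.blocks for e in block.planted_edges()],
        factor_effects=_factor_effect_map(config),
        expected_cell_shares={c: dict(s) for c, s in config.cell_shares.items()},
    )
    return table, taxonomy, design, truth


# ---------------------------------------------------------------------------
# Default profile
# ---------------------------------------------------------------------------

_BACTERIA = [
    ("Massilia", "Proteobacteria", "Oxalobacteraceae"),
    ("Rhizobium", "Proteobacteria", "Rhizobiaceae"),
    ("Devosia", "Proteobacteria", "Hyphomicrobiaceae"),
    ("Ensifer", "Proteobacteria", "Rhizobiaceae"),
    ("Brevundimonas", "Proteobacteria", "Caulobacteraceae"),
    ("Bdellovibrio", "Proteobacteria", "Bdellovibrionaceae"),
    ("Paucimonas", "Proteobacteria", "Burkholderiaceae"),
    ("Bacillus", "Firmicutes", "Bacillaceae"),
    ("Tumebacillus", "Firmicutes", "Alicyclobacillaceae"),
    ("Paenibacillus", "Firmicutes", "Paenibacillaceae"),
    ("Paenisporosarcina", "Firmicutes", "Planococcaceae"),
    ("Adhaeribacter", "Bacteroidetes", "Hymenobacteraceae"),
    ("Flavisolibacter", "Bacteroidetes", "Chitinophagaceae"),
    ("Pedobacter", "Bacteroidetes", "Sphingobacteriaceae"),
    ("norank_f__Chitinophagaceae", "Bacteroidetes", "Chitinophagaceae"),
    ("Pseudarthrobacter", "Actinobacteria", "Micrococcaceae"),
    ("norank_o__Acidimicrobiales", "Actinobacteria", "Acidimicrobiaceae"),
    ("norank_f__Anaerolineaceae", "Chloroflexi", "Anaerolineaceae"),
    ("Microcoleus", "Cyanobacteria", "Microcoleaceae"),
    ("Chthoniobacter", "Verrucomicrobia", "Chthoniobacteraceae"),
    ("Nitrospira", "Nitrospirae", "Nitrospiraceae"),
    ("norank_c__Gemmatimonadetes", "Gemmatimonadetes", "Gemmatimonadaceae"),
    ("Gp6", "Acidobacteria", "Acidobacteriaceae"),
    ("Gemmatimonas", "Gemmatimonadetes", "Gemmatimonadaceae"),
]

#: phyla concentrated on when indigenous biomass is low
_L_DOMINANT_PHYLA = {"Proteobacteria", "Firmicutes", "Bacteroidetes"}

_FUNGI = [
    ("Fusarium", "Ascomycota", "Nectriaceae", "Fusarium"),
    ("unclassified_f__Nectriaceae", "Ascomycota", "Nectriaceae", None),
    ("Cystofilobasidiaceae", "Basidiomycota", "Cystofilobasidiaceae", None),
    ("Chaetomiaceae", "Ascomycota", "Chaetomiaceae", None),
    ("Microascaceae", "Ascomycota", "Microascaceae", None),
    ("Lasiosphaeriaceae", "Ascomycota", "Lasiosphaeriaceae", None),
    ("Trichocomaceae", "Ascomycota", "Trichocomaceae", None),
    ("Mortierellaceae", "Zygomycota", "Mortierellaceae", None),
    ("Rhizophlyctidaceae", "Chytridiomycota", "Rhizophlyctidaceae", None),
    ("Hypocreaceae", "Ascomycota", "Hypocreaceae", None),
    ("Sporormiaceae", "Ascomycota", "Sporormiaceae", None),
    ("Ceratobasidiaceae", "Basidiomycota", "Ceratobasidiaceae", None),
    ("unclassified_p__Ascomycota", "Ascomycota", None, None),
    ("unclassified_k__Fungi", None, None, None),
]

#: within-fungi mean share of the Fusarium-type taxon per rhizosphere cell
_FUSARIUM_SHARE = {
    NATIVE: 0.0159,
    "NL_SR": 0.8741, "CL_SR": 0.1602, "OL_SR": 0.0503,
    "NM_SR": 0.0827, "CM_SR": 0.0928, "OM_SR": 0.1507,
    "NH_SR": 0.0236, "CH_SR": 0.1628, "OH_SR": 0.0384,
}
#: companion family-level pathogen shares (rhizosphere cells)
_NECTRIACEAE_SHARE = {
    NATIVE: 0.0014,
    "NL_SR": 0.0186, "CL_SR": 0.5, "OL_SR": 0.0434,
    "NM_SR": 0.45, "CM_SR": 0.0877, "OM_SR": 0.35,
    "NH_SR": 0.2637, "CH_SR": 0.1324, "OH_SR": 0.1304,
}
_FUSARIUM_SB = {"L": 0.035, "M": 0.025, "H": 0.020}
_NECTRIACEAE_SB = {"L": 0.020, "M": 0.020, "H": 0.015}


def _bacteria_shares(cell: str) -> dict[str, float]:
    ismb, _fert, _hab = _cell_factors(cell)
    base = {}
    for name, phylum, _family in _BACTERIA:
        weight = 1.0
        if name in ("Massilia", "Bacillus", "Adhaeribacter", "Pseudarthrobacter"):
            weight = 2.0
        base[name] = weight
    if ismb == "L":
        # mass concentrates on three dominant phyla
        for name, phylum, _family in _BACTERIA:
            if phylum in _L_DOMINANT_PHYLA:
                base[name] *= 5.0
            else:
                base[name] *= 0.5
    elif ismb == "M":
        for name, phylum, _family in _BACTERIA:
            if phylum in _L_DOMINANT_PHYLA:
                base[name] *= 1.5
    total = sum(base.values())
    return {name: value / total for name, value in base.items()}


def _fungi_shares(cell: str) -> dict[str, float]:
    ismb, _fert, hab = _cell_factors(cell)
    base = {name: 1.0 for name, *_ in _FUNGI}
    base["Cystofilobasidiaceae"] = 2.0
    base["Chaetomiaceae"] = 1.5
    base["unclassified_k__Fungi"] = 1.5
    if cell == NATIVE:
        fus, nec = _FUSARIUM_SHARE[NATIVE], _NECTRIACEAE_SHARE[NATIVE]
    elif hab == "SR":
        fus = _FUSARIUM_SHARE[cell]
        nec = _NECTRIACEAE_SHARE[cell]
    else:
        fus = _FUSARIUM_SB[ismb]
        nec = _NECTRIACEAE_SB[ismb]
    rest = {name: w for name, w in base.items()
            if name not in ("Fusarium", "unclassified_f__Nectriaceae")}
    scale = (1.0 - fus - nec) / sum(rest.values())
    shares = {name: w * scale for name, w in rest.items()}
    shares["Fusarium"] = fus
    shares["unclassified_f__Nectriaceae"] = nec
    return shares


def _bacteria_lineage(phylum: str, family: str, genus: str) -> str:
    return f"d__Bacteria;p__{phylum};c__;o__;f__{family};g__{genus}"


def _fungi_lineage(phylum, family, genus) -> str:
    parts = ["k__Fungi"]
    parts.append(f"p__{phylum}" if phylum else "p__")
    parts.extend(["c__", "o__"])
    parts.append(f"f__{family}" if family else "f__")
    parts.append(f"g__{genus}" if genus else "g__")
    return ";".join(parts)


def default_paper_profile(seed: int = DEFAULT_SEED) -> SimulationConfig:
    """Bundled configuration emulating the study's composition patterns.

    Low-biomass cells concentrate bacterial mass on three dominant phyla,
    moderate/high cells spread it over seven; rhizosphere low-biomass cells
    give the Fusarium-type taxon its configured high share (0.8741 for the
    no-fertilizer low-biomass rhizosphere cell).
    """
    taxa = [
        TaxonSpec(name, "bacteria", _bacteria_lineage(phylum, family, name))
        for name, phylum, family in _BACTERIA
    ]
    taxa += [
        TaxonSpec(name, "fungi", _fungi_lineage(phylum, family, genus))
        for name, phylum, family, genus in _FUNGI
    ]
    shares = {}
    for cell in cell_codes():
        cell_share = _bacteria_shares(cell)
        cell_share.update(_fungi_shares(cell))
        shares[cell] = cell_share
    blocks = [
        AssociationBlock(("Nitrospira", "norank_c__Gemmatimonadetes",
                          "Pseudarthrobacter"), 1.5, 1),
        AssociationBlock(("Microcoleus", "Chthoniobacter"), 1.5, 1),
        AssociationBlock(("Devosia", "Ensifer"), 1.5, 1),
        AssociationBlock(("Rhizobium", "Massilia"), 1.5, -1),
        AssociationBlock(("Rhizophlyctidaceae", "Lasiosphaeriaceae",
                          "Trichocomaceae"), 1.5, 1),
        AssociationBlock(("Chaetomiaceae", "Mortierellaceae"), 1.5, 1),
        AssociationBlock(("Cystofilobasidiaceae", "Sporormiaceae"), 1.5, -1),
    ]
    covariates = [
        CovariateSpec("TN", 0.45, 0.01,
                      ismb_effect={"L": 0.0, "M": 0.04, "H": 0.05},
                      fertilizer_effect={"N": 0.0, "C": 0.03, "O": 0.01},
                      native_value=0.45),
        CovariateSpec("TC", 28.7, 0.8,
                      ismb_effect={"L": 0.0, "M": 8.5, "H": 2.0},
                      fertilizer_effect={"N": 0.0, "C": 0.5, "O": 2.5},
                      native_value=31.6),
        CovariateSpec("NH4", 0.12, 0.01,
                      ismb_effect={"L": 0.05, "M": 0.02, "H": 0.0},
                      habitat_effect={"SB": 0.0, "SR": -0.02},
                      native_value=0.10),
        CovariateSpec("NO3", 2.6, 0.08,
                      ismb_effect={"L": -0.5, "M": 0.0, "H": 0.4},
                      fertilizer_effect={"N": 0.0, "C": 0.8, "O": 1.5},
                      habitat_effect={"SB": 0.0, "SR": -0.6},
                      native_value=2.65),
        CovariateSpec("AP", 27.4, 1.0,
                      ismb_effect={"L": 0.0, "M": 5.0, "H": 15.0},
                      fertilizer_effect={"N": 0.0, "C": 20.0, "O": 45.0},
                      native_value=27.41),
        CovariateSpec("AK", 221.0, 2.0,
                      ismb_effect={"L": 0.0, "M": -3.5, "H": -2.6},
                      habitat_effect={"SB": 0.0, "SR": -6.0},
                      native_value=197.18),
        CovariateSpec("dry_matter", 2.0, 0.05,
                      ismb_effect={"L": 0.0, "M": 0.5, "H": 1.0},
                      fertilizer_effect={"N": 0.0, "C": 0.6, "O": 0.8},
                      interaction={("O", "M"): 0.4, ("O", "H"): 1.2},
                      native_value=2.0),
        CovariateSpec("stem_length", 20.0, 0.4,
                      ismb_effect={"L": 0.0, "M": 2.0, "H": 4.0},
                      fertilizer_effect={"N": 0.0, "C": 1.5, "O": 2.5},
                      native_value=20.0),
    ]
    return SimulationConfig(
        taxa=taxa,
        cell_shares=shares,
        blocks=blocks,
        covariates=covariates,
        seed=seed,
    )


def null_profile(n_taxa: int = 20, seed: int = DEFAULT_SEED,
                 replicates: int = 3) -> SimulationConfig:
    """Flat configuration: identical cell means, no association blocks.

    Used for type-I-error calibration of the permutation tests.
    """
    taxa = [
        TaxonSpec(f"t{i:02d}", "bacteria", _bacteria_lineage("Proteobacteria", "F", f"t{i:02d}"))
        for i in range(n_taxa)
    ]
    flat = {t.name: 1.0 / n_taxa for t in taxa}
    shares = {cell: dict(flat) for cell in cell_codes()}
    return SimulationConfig(taxa=taxa, cell_shares=shares, blocks=[],
                            covariates=[], replicates=replicates, seed=seed)
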