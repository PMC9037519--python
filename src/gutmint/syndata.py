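"""Synthetic cohort generator: microbiome, metabolome and phenotypes.

Emulates a two-class (IBS vs HC) case-control cohort with matched fecal
microbiome and metabolome measurements plus a wide block of mixed-type
phenotype variables:

* species-level relative abundances are log-normal compositions -- Gaussian
  log-abundances, Bernoulli sparsity masking, exponentiation and closure to
  row sum 1; class effects are planted on the log scale *before* closure so
  that ``effect_size`` stays interpretable in units of within-group SD,
* metabolite intensities are positive log-normals with class effects on the
  log scale; one designated polymer-like feature can be spiked far above its
  mean in selected samples to mimic polyethylene-glycol contamination
  (``spike_sd`` defaults to 5000 within-group SDs, i.e. a raw intensity
  thousands of times the feature mean: a laxative polymer peak dominates a
  spectrum by orders of magnitude, and anything weaker barely registers
  once intensities are log-transformed for outlier screening),
* latent patient subgroups exist among cases only: the subgroup-signature
  features (disjoint from the class-informative subsets) are split into one
  exclusive marker block per subgroup, and members of a subgroup gain
  ``subgroup_shift`` SD on their own block -- subtype-specific signatures
  with symmetric between-subgroup geometry; a subset of phenotype
  variables is linked to the subgroups.

All randomness flows from ``SynthConfig.seed`` through spawned
``numpy.random.SeedSequence`` streams, so equal configs give bit-identical
output regardless of which generator functions are called or in what order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .tables_io import (
    METABOLITE,
    TAXON,
    FeatureTable,
    PhenotypeTable,
    TaxonLineage,
)

CASE = "IBS"
CONTROL = "HC"

#: feature id of the polymer-like metabolite (always the last metabolite)
POLYMER_FEATURE = "polyethylene_glycol"


@dataclass
class SynthConfig:
    """Parameters of the synthetic cohort.

    Counts are per block; ``effect_size`` and ``subgroup_shift`` are
    standardized mean shifts in units of the within-group SD on the log
    scale.  Defaults emulate the structure of a two-class fecal cohort:
    ~100 samples per class, 38 bacterial families, 49 identified
    metabolites and ~200 phenotype variables.
    """

    n_per_class: int = 100
    n_species: int = 120
    n_families: int = 38
    n_metabolites: int = 49
    n_informative_taxa: int = 10
    n_informative_families: int = 0
    n_informative_metabolites: int = 10
    effect_size: float = 1.0
    n_subgroups: int = 3
    subgroup_shift: float = 1.0
    n_subgroup_taxa: int = 20
    n_subgroup_metabolites: int = 16
    n_pheno_continuous: int = 150
    n_pheno_binary: int = 50
    n_pheno_linked: int = 6
    missing_rate: float = 0.0
    n_outliers: int = 0
    sparsity: float = 0.3
    spike_sd: float = 5000.0
    family_concentration: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_per_class": self.n_per_class,
            "n_species": self.n_species,
            "n_families": self.n_families,
            "n_metabolites": self.n_metabolites,
            "n_informative_taxa": self.n_informative_taxa,
            "n_informative_metabolites": self.n_informative_metabolites,
            "n_subgroups": self.n_subgroups,
            "n_subgroup_taxa": self.n_subgroup_taxa,
            "n_subgroup_metabolites": self.n_subgroup_metabolites,
            "n_pheno_continuous": self.n_pheno_continuous,
            "n_pheno_binary": self.n_pheno_binary,
            "n_pheno_linked": self.n_pheno_linked,
            "n_outliers": self.n_outliers,
        }
        for name, value in counts.items():
            if value < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_informative_taxa + self.n_subgroup_taxa > self.n_species:
            raise ValueError(
                "n_informative_taxa + n_subgroup_taxa exceeds n_species"
            )
        if self.n_informative_families > self.n_families:
            raise ValueError("n_informative_families exceeds n_families")
        if (
            self.n_informative_metabolites + self.n_subgroup_metabolites
            > self.n_metabolites
        ):
            raise ValueError(
                "n_informative_metabolites + n_subgroup_metabolites exceeds "
                "n_metabolites"
            )
        if self.n_pheno_linked > self.n_pheno_continuous + self.n_pheno_binary:
            raise ValueError("n_pheno_linked exceeds total phenotype count")
        if self.effect_size < 0 or self.subgroup_shift < 0:
            raise ValueError("effect sizes must be non-negative")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if not 0 <= self.sparsity < 1:
            raise ValueError("sparsity must be in [0, 1)")
        if self.spike_sd < 20:
            raise ValueError("spike_sd must be >= 20 within-group SDs")
        if self.n_families < 1 or self.n_families > self.n_species:
            raise ValueError("need 1 <= n_families <= n_species")
        if self.n_outliers > 2 * self.n_per_class:
            raise ValueError("n_outliers exceeds sample count")


@dataclass
class GroundTruth:
    """Planted structure of one synthetic cohort."""

    class_labels: pd.Series
    subgroup_labels: pd.Series
    informative_taxa: list[str]
    informative_metabolites: list[str]
    subgroup_taxa: list[str]
    subgroup_metabolites: list[str]
    taxa_effect_signs: dict[str, int]
    metabolite_effect_signs: dict[str, int]
    subgroup_taxa_signs: np.ndarray  # (n_subgroups, n_subgroup_taxa)
    subgroup_metabolite_signs: np.ndarray
    phenotype_linkage: dict[str, float]
    outlier_samples: list[str]
    seed: int = 0

    def __post_init__(self) -> None:
        case_ids = set(self.class_labels.index[self.class_labels == CASE])
        if not set(self.subgroup_labels.index) <= case_ids:
            raise ValueError("subgroup labels defined for non-case samples")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.class_labels.index)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "class_labels": self.class_labels.to_dict(),
            "subgroup_labels": {
                k: int(v) for k, v in self.subgroup_labels.items()
            },
            "informative_taxa": self.informative_taxa,
            "informative_metabolites": self.informative_metabolites,
            "subgroup_taxa": self.subgroup_taxa,
            "subgroup_metabolites": self.subgroup_metabolites,
            "taxa_effect_signs": self.taxa_effect_signs,
            "metabolite_effect_signs": self.metabolite_effect_signs,
            "subgroup_taxa_signs": np.asarray(self.subgroup_taxa_signs)
            .astype(int)
            .tolist(),
            "subgroup_metabolite_signs": np.asarray(
                self.subgroup_metabolite_signs
            )
            .astype(int)
            .tolist(),
            "phenotype_linkage": self.phenotype_linkage,
            "outlier_samples": self.outlier_samples,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


# ---------------------------------------------------------------------------
# internal helpers
# ---------------------------------------------------------------------------


def _streams(config: SynthConfig) -> dict[str, np.random.Generator]:
    """Independent, reproducible random streams per generation stage."""
    root = np.random.SeedSequence(config.seed)
    names = ("design", "microbiome", "metabolome", "phenotypes")
    children = root.spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _signature_blocks(n_subgroups: int, n_features: int) -> np.ndarray:
    """0/1 membership of subgroup-signature features (one block per group)."""
    signs = np.zeros((max(n_subgroups, 1), n_features), dtype=int)
    for j in range(n_features):
        signs[j % max(n_subgroups, 1), j] = 1
    return signs


def _design(config: SynthConfig) -> GroundTruth:
    """Draw all planted structure (shared by the three generators)."""
    rng = _streams(config)["design"]
    n = 2 * config.n_per_class
    samples = [f"S{i:04d}" for i in range(n)]
    labels = pd.Series(
        [CONTROL] * config.n_per_class + [CASE] * config.n_per_class,
        index=samples,
        name="diagnosis",
    )
    cases = [s for s in samples if labels[s] == CASE]

    if config.n_subgroups >= 1 and len(cases):
        reps = np.resize(np.arange(config.n_subgroups), len(cases))
        sub = pd.Series(rng.permutation(reps), index=cases, name="subgroup")
    else:
        sub = pd.Series(dtype=int, name="subgroup")

    species = [f"sp{j:04d}" for j in range(config.n_species)]
    metabolites = [f"met{j:03d}" for j in range(config.n_metabolites)]
    if config.n_metabolites >= 1:
        metabolites[-1] = POLYMER_FEATURE

    if config.n_informative_families > 0:
        # coherent family-level signal: every species of the chosen
        # families shifts with one sign per family
        lineage = _make_lineage(config, species)
        fams = rng.choice(
            config.n_families, size=config.n_informative_families, replace=False
        )
        fam_labels = {f"fam{j:02d}" for j in fams}
        fam_sign = {f: int(s) for f, s in zip(
            sorted(fam_labels), rng.choice([-1, 1], size=len(fam_labels))
        )}
        family_of = lineage.labels_at("family")
        info_taxa = [sp for sp in species if family_of[sp] in fam_labels]
        taxa_signs_family = {sp: fam_sign[family_of[sp]] for sp in info_taxa}
        remaining = [sp for sp in species if sp not in set(info_taxa)]
        if config.n_subgroup_taxa > len(remaining):
            raise ValueError("too few species left for subgroup signatures")
        sub_idx = rng.choice(
            len(remaining), size=config.n_subgroup_taxa, replace=False
        )
        sub_taxa = [remaining[j] for j in sub_idx]
    else:
        taxa_signs_family = None
        pick_taxa = rng.choice(
            config.n_species,
            size=config.n_informative_taxa + config.n_subgroup_taxa,
            replace=False,
        )
        info_taxa = [species[j] for j in pick_taxa[: config.n_informative_taxa]]
        sub_taxa = [species[j] for j in pick_taxa[config.n_informative_taxa :]]
    # keep the polymer feature out of the planted metabolite subsets
    eligible_mets = np.arange(max(config.n_metabolites - 1, 0))
    n_pick = config.n_informative_metabolites + config.n_subgroup_metabolites
    if n_pick > len(eligible_mets):
        raise ValueError("too few metabolites besides the polymer feature")
    pick_mets = rng.choice(eligible_mets, size=n_pick, replace=False)
    info_mets = [
        metabolites[j] for j in pick_mets[: config.n_informative_metabolites]
    ]
    sub_mets = [
        metabolites[j] for j in pick_mets[config.n_informative_metabolites :]
    ]

    if taxa_signs_family is not None:
        taxa_signs = taxa_signs_family
    else:
        taxa_signs = {
            f: int(s)
            for f, s in zip(info_taxa, rng.choice([-1, 1], size=len(info_taxa)))
        }
    met_signs = {
        f: int(s)
        for f, s in zip(info_mets, rng.choice([-1, 1], size=len(info_mets)))
    }
    # each subgroup owns an exclusive marker block (round-robin split), so
    # subgroup centroids are symmetric: subtype-specific signatures
    sub_taxa_signs = _signature_blocks(config.n_subgroups, len(sub_taxa))
    sub_met_signs = _signature_blocks(config.n_subgroups, len(sub_mets))

    pheno_names = [f"pheno_c{j:03d}" for j in range(config.n_pheno_continuous)]
    pheno_names += [f"pheno_b{j:03d}" for j in range(config.n_pheno_binary)]
    linked = rng.choice(
        len(pheno_names), size=config.n_pheno_linked, replace=False
    )
    linkage = {pheno_names[j]: config.subgroup_shift for j in sorted(linked)}

    outliers = [
        samples[j]
        for j in sorted(
            rng.choice(n, size=config.n_outliers, replace=False)
        )
    ]

    return GroundTruth(
        class_labels=labels,
        subgroup_labels=sub,
        informative_taxa=info_taxa,
        informative_metabolites=info_mets,
        subgroup_taxa=sub_taxa,
        subgroup_metabolites=sub_mets,
        taxa_effect_signs=taxa_signs,
        metabolite_effect_signs=met_signs,
        subgroup_taxa_signs=sub_taxa_signs,
        subgroup_metabolite_signs=sub_met_signs,
        phenotype_linkage=linkage,
        outlier_samples=outliers,
        seed=config.seed,
    )


def _make_lineage(config: SynthConfig, species: list[str]) -> TaxonLineage:
    """Deterministic nested lineage: species -> genus -> family -> ... ."""
    fam_of: list[int] = list(range(config.n_families))  # each family occupied
    extra = len(species) - config.n_families
    if extra > 0:
        # remaining species spread over families with a skewed profile
        weights = 1.0 / (1.0 + np.arange(config.n_families))
        weights /= weights.sum()
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 101])
        )
        fam_of += list(rng.choice(config.n_families, size=extra, p=weights))
    rows = []
    within: dict[int, int] = {}
    for sp, fj in zip(species, fam_of):
        k = within.get(fj, 0)
        within[fj] = k + 1
        fam = f"fam{fj:02d}"
        rows.append(
            {
                "kingdom": "Bacteria",
                "phylum": f"phy{fj // 8:02d}",
                "class": f"cls{fj // 4:02d}",
                "order": f"ord{fj // 2:02d}",
                "family": fam,
                "genus": f"{fam}_g{k // 2}",
            }
        )
    table = pd.DataFrame(rows, index=pd.Index(species, name="species_id"))
    return TaxonLineage(table)


def _apply_case_shifts(
    log_x: np.ndarray,
    feature_ids: list[str],
    truth: GroundTruth,
    informative: list[str],
    signs: dict[str, int],
    effect_size: float,
    subgroup_features: list[str],
    subgroup_signs: np.ndarray,
    subgroup_shift: float,
) -> None:
    """Add class and subgroup mean shifts (in SD units) in place."""
    col = {f: j for j, f in enumerate(feature_ids)}
    case_rows = np.array(
        [
            i
            for i, s in enumerate(truth.sample_ids)
            if truth.class_labels.iloc[i] == CASE
        ]
    )
    if effect_size > 0 and len(case_rows):
        for f in informative:
            log_x[case_rows, col[f]] += signs[f] * effect_size
    if subgroup_shift > 0 and len(subgroup_features) and len(truth.subgroup_labels):
        for i, sample in enumerate(truth.sample_ids):
            if sample not in truth.subgroup_labels.index:
                continue
            g = int(truth.subgroup_labels[sample])
            for jj, f in enumerate(subgroup_features):
                log_x[i, col[f]] += subgroup_signs[g, jj] * subgroup_shift


# ---------------------------------------------------------------------------
# public generators
# ---------------------------------------------------------------------------


def generate_microbiome(
    config: SynthConfig,
) -> tuple[FeatureTable, TaxonLineage, GroundTruth]:
    """Species-level relative abundances plus lineage and ground truth.

    Log-abundances are ``N(mu_j, 1)`` with per-species base means
    ``mu_j ~ N(0, 2^2)``; class and subgroup shifts are added on the log
    scale, then a Bernoulli sparsity mask (``config.sparsity``) zeroes
    species per sample, and rows are closed to sum 1.

    With ``n_informative_families > 0`` the generator is family-structured:
    class effects shift family log-totals and species are the family total
    times a per-sample Dirichlet composition, so species-level variation
    is within-family replacement that cancels at the family rank.
    """
    truth = _design(config)
    rng = _streams(config)["microbiome"]
    n = 2 * config.n_per_class
    species = [f"sp{j:04d}" for j in range(config.n_species)]
    lineage = _make_lineage(config, species)

    if config.n_informative_families > 0:
        # family-structured mode: class effects act on family log-totals;
        # species-level variation is within-family replacement (Dirichlet
        # composition), which cancels when abundances are aggregated to
        # the family rank -- functional redundancy among related species
        family_of = lineage.labels_at("family")
        fam_labels = sorted(set(family_of))
        info_fams = {family_of[sp] for sp in truth.informative_taxa}
        mu_f = rng.normal(0.0, 2.0, size=len(fam_labels))
        abundance = np.zeros((n, config.n_species))
        col = {sp: j for j, sp in enumerate(species)}
        case_rows = (truth.class_labels == CASE).to_numpy()
        for fj, fam in enumerate(fam_labels):
            members = [sp for sp in species if family_of[sp] == fam]
            log_total = mu_f[fj] + rng.normal(0.0, 1.0, size=n)
            if fam in info_fams and config.effect_size > 0:
                sign = truth.taxa_effect_signs[members[0]]
                log_total = log_total + np.where(
                    case_rows, sign * config.effect_size, 0.0
                )
            base = np.exp(rng.normal(0.0, 2.0, size=len(members)))
            base /= base.sum()
            if len(members) == 1:
                weights = np.ones((n, 1))
            else:
                weights = rng.dirichlet(
                    config.family_concentration * len(members) * base, size=n
                )
                weights = np.maximum(weights, 1e-12)
            for k, sp in enumerate(members):
                abundance[:, col[sp]] = np.exp(log_total) * weights[:, k]
        # subgroup signatures remain species-level (multiplicative shift)
        if config.subgroup_shift > 0 and len(truth.subgroup_taxa):
            log_x = np.log(abundance)
            _apply_case_shifts(
                log_x,
                species,
                truth,
                [],
                {},
                0.0,
                truth.subgroup_taxa,
                truth.subgroup_taxa_signs,
                config.subgroup_shift,
            )
            abundance = np.exp(log_x)
    else:
        mu = rng.normal(0.0, 2.0, size=config.n_species)
        log_x = mu[None, :] + rng.normal(0.0, 1.0, size=(n, config.n_species))
        _apply_case_shifts(
            log_x,
            species,
            truth,
            truth.informative_taxa,
            truth.taxa_effect_signs,
            config.effect_size,
            truth.subgroup_taxa,
            truth.subgroup_taxa_signs,
            config.subgroup_shift,
        )
        abundance = np.exp(log_x)
    if config.sparsity > 0:
        mask = rng.random(size=abundance.shape) >= config.sparsity
        # guarantee at least one positive entry per sample
        dead = ~mask.any(axis=1)
        if dead.any():
            mask[dead, np.argmax(abundance[dead], axis=1)] = True
        abundance = abundance * mask
    abundance = abundance / abundance.sum(axis=1, keepdims=True)
    data = pd.DataFrame(abundance, index=truth.sample_ids, columns=species)
    table = FeatureTable(data, blocks=TAXON, rank="species")
    return table, lineage, truth


def generate_metabolome(config: SynthConfig, truth: GroundTruth) -> FeatureTable:
    """Positive log-normal metabolite intensities consistent with *truth*.

    The last feature (:data:`POLYMER_FEATURE`) represents a polymer
    contaminant; in ``truth.outlier_samples`` it is set
    ``config.spike_sd`` within-group SDs above its mean (raw scale).
    """
    expected = _design(config)
    if expected.sample_ids != truth.sample_ids:
        raise ValueError("truth does not match config (sample mismatch)")
    if config.n_metabolites == 0:
        raise ValueError("n_metabolites must be >= 1")
    rng = _streams(config)["metabolome"]
    n = 2 * config.n_per_class
    metabolites = [f"met{j:03d}" for j in range(config.n_metabolites)]
    metabolites[-1] = POLYMER_FEATURE

    mu = rng.normal(0.0, 1.0, size=config.n_metabolites)
    log_y = mu[None, :] + rng.normal(0.0, 1.0, size=(n, config.n_metabolites))
    _apply_case_shifts(
        log_y,
        metabolites,
        truth,
        truth.informative_metabolites,
        truth.metabolite_effect_signs,
        config.effect_size,
        truth.subgroup_metabolites,
        truth.subgroup_metabolite_signs,
        config.subgroup_shift,
    )
    intensity = np.exp(log_y)
    if truth.outlier_samples:
        j = config.n_metabolites - 1
        col = intensity[:, j]
        spike = col.mean() + config.spike_sd * col.std(ddof=0)
        rows = [truth.sample_ids.index(s) for s in truth.outlier_samples]
        intensity[rows, j] = spike
    data = pd.DataFrame(intensity, index=truth.sample_ids, columns=metabolites)
    return FeatureTable(data, blocks=METABOLITE, rank=None)


def generate_phenotypes(config: SynthConfig, truth: GroundTruth) -> PhenotypeTable:
    """Mixed continuous/binary phenotype block with subgroup-linked variables.

    Continuous variables are standard normal; a linked continuous variable
    gains ``g * subgroup_shift`` for cases in subgroup ``g``.  Binary
    variables are Bernoulli draws whose log-odds shift by the same pattern.
    Missing cells are inserted completely at random at ``missing_rate``.
    """
    expected = _design(config)
    if expected.sample_ids != truth.sample_ids:
        raise ValueError("truth does not match config (sample mismatch)")
    rng = _streams(config)["phenotypes"]
    n = 2 * config.n_per_class
    names_c = [f"pheno_c{j:03d}" for j in range(config.n_pheno_continuous)]
    names_b = [f"pheno_b{j:03d}" for j in range(config.n_pheno_binary)]

    sub_of = np.full(n, -1)
    for i, s in enumerate(truth.sample_ids):
        if s in truth.subgroup_labels.index:
            sub_of[i] = int(truth.subgroup_labels[s])

    cols = {}
    for name in names_c:
        x = rng.normal(0.0, 1.0, size=n)
        if name in truth.phenotype_linkage:
            shift = truth.phenotype_linkage[name]
            x = x + np.where(sub_of >= 0, sub_of, 0.0) * shift
        cols[name] = x
    for name in names_b:
        base = rng.uniform(0.25, 0.75)
        logit = np.log(base / (1 - base)) * np.ones(n)
        if name in truth.phenotype_linkage:
            shift = truth.phenotype_linkage[name]
            g = np.where(sub_of >= 0, sub_of, 0.0)
            center = (config.n_subgroups - 1) / 2 if config.n_subgroups else 0
            logit = logit + np.where(sub_of >= 0, (g - center) * shift, 0.0)
        p = 1.0 / (1.0 + np.exp(-logit))
        cols[name] = (rng.random(n) < p).astype(float)

    data = pd.DataFrame(cols, index=truth.sample_ids)[names_c + names_b]
    if config.missing_rate > 0:
        mask = rng.random(size=data.shape) < config.missing_rate
        data = data.mask(mask)
    types = pd.Series(
        ["continuous"] * len(names_c) + ["binary"] * len(names_b),
        index=names_c + names_b,
    )
    return PhenotypeTable(data, types)


def generate_all(config: SynthConfig) -> dict:
    """Convenience wrapper generating every block of one cohort."""
    microbiome, lineage, truth = generate_microbiome(config)
    metabolome = generate_metabolome(config, truth)
    phenotypes = generate_phenotypes(config, truth)
    return {
        "config": config,
        "truth": truth,
        "microbiome": microbiome,
        "lineage": lineage,
        "metabolome": metabolome,
        "phenotypes": phenotypes,
    }
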