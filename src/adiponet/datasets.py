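"""Synthetic RNA-Seq studies with planted co-expression structure.

The generator emulates the design of a three-group obesity study: 36
subcutaneous adipose tissue samples (12 lean, 12 intermediate, 12 obese),
negative-binomial gene-level counts, co-expression modules driven by shared
latent factors, latent-factor/trait correlations, a block of hub genes
co-expressed only in the obese group, and candidate regulator genes whose
expression tracks the sample partition of the cluster they drive.  Every
planted feature is recorded in a :class:`PlantedTruth` so recovery can be
scored exactly.

Latent model
------------
Gene log2-expression within a module is ``sigma * (sqrt(w)*f + sqrt(1-w)*e)``
where ``f`` is the module's latent factor (one value per sample), ``e`` is
i.i.d. Gaussian noise and ``w`` is the target within-module pairwise
correlation; the loading ``sqrt(w)`` makes the expected pairwise correlation
exactly ``w``.  Traits are generated from the factors at their configured
correlation.  Counts are drawn negative-binomial around the exponentiated
log-means with variance ``mu + phi*mu**2``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "PlantedTruth",
    "SyntheticStudy",
    "simulate_study",
    "write_study",
    "read_study",
    "write_gmt",
    "read_gmt",
]

GROUPS = ("lean", "intermediate", "obese")

#: trait names cycled through when assigning module -> trait targets; the
#: first is the aggregate obesity index whose group means are kept monotone
DEFAULT_TRAITS = (
    "obesity_index",
    "weight",
    "fasting_glucose",
    "abdominal_circumference",
    "fat_dxa",
)

# location/scale used to print traits in plausible units; correlations are
# invariant to these
_TRAIT_UNITS = {
    "obesity_index": (0.0, 2.0),
    "weight": (95.0, 15.0),
    "fasting_glucose": (5.5, 0.8),
    "abdominal_circumference": (123.0, 11.0),
    "fat_dxa": (2300.0, 700.0),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a synthetic study.

    Defaults describe the reference study shape: 36 samples in three groups
    of 12 with balanced gender, five planted modules, a 10-gene obese-only
    hub block and two planted regulators among 200 candidates.
    """

    n_genes: int = 1000
    n_samples_per_group: int = 12
    module_sizes: tuple[int, ...] = (120, 100, 90, 80, 70)
    #: per-module target correlation between latent factor and its trait
    module_trait_cor: tuple[float, ...] = (0.7, 0.6, -0.5, 0.5, 0.4)
    within_module_cor: float = 0.6
    n_diff_hubs: int = 10
    #: size of the mirrored lean-only co-expressed block; condition-specific
    #: structure on both sides keeps the per-sub-network max-k normalization
    #: meaningful (a sub-network without hubs has no connectivity scale)
    n_lean_hubs: int = 30
    n_regulators: int = 2
    nb_dispersion: float = 0.02
    #: log2 scale; per-gene baselines are drawn uniformly +-1.5 around this
    mean_log_expression: float = 7.0
    seed: int = 0
    # --- secondary knobs (study conditions, rarely changed) ---
    #: total log2 SD of genes carrying planted signal (module/hub/regulator)
    expression_sd: float = 0.7
    #: log2 SD of background genes; below the regulator-stage SD filter so
    #: the variance-filter cascade mirrors a real study's shrinking gene set
    background_sd: float = 0.4
    #: pairwise correlation of the obese-only hub block (tightly co-regulated)
    diff_hub_cor: float = 0.98
    #: log2 SD of the hub block; hubs are strongly regulated, and the larger
    #: dynamic range keeps their tight correlation visible through count noise
    hub_expression_sd: float = 1.4
    #: log2 up-shift of hub genes in obese samples (drives differential expression)
    diff_hub_shift: float = 2.0
    #: number of listed candidate regulators (planted ones plus decoys)
    n_candidate_regulators: int = 200
    regulator_effect: float = 2.0
    regulator_noise_sd: float = 0.5
    #: noise mixed into the binary partition underlying regulator-driven factors
    partition_noise_sd: float = 0.1
    #: per-gene gender effect SD (log2), removed by the preprocessing stage
    gender_effect_sd: float = 0.2
    #: background genes load weakly on this many shared "global" factors
    #: (cell-composition-like variation), giving the connectivity
    #: distribution the heavy-tailed continuum seen in real data
    n_global_factors: int = 3
    #: upper bound of the background loading (squared = max variance share);
    #: kept low enough that background co-expression never coheres into
    #: module-strength blocks
    background_loading_max: float = 0.4
    #: fraction of genes simulated at near-zero expression (low-count filter fodder)
    frac_low_expressed: float = 0.05
    #: fraction of background genes simulated as very highly expressed
    #: "housekeeping" mass; real libraries are dominated by a stable set of
    #: high-abundance transcripts, which keeps library size insensitive to
    #: the planted factors (otherwise CPM normalization would absorb signal)
    frac_housekeeping: float = 0.02
    n_background_terms: int = 30

    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_samples_per_group <= 0:
            raise ValueError("n_genes and n_samples_per_group must be positive")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be non-negative")
        if not 0 < self.within_module_cor <= 1:
            raise ValueError("within_module_cor must lie in (0, 1]")
        if len(self.module_trait_cor) != len(self.module_sizes):
            raise ValueError("module_trait_cor must align with module_sizes")
        for r in self.module_trait_cor:
            if not -1 <= r <= 1:
                raise ValueError(f"module_trait_cor {r} outside [-1, 1]")
        n_low = int(round(self.frac_low_expressed * self.n_genes))
        planted = (
            sum(self.module_sizes) + self.n_diff_hubs + self.n_lean_hubs + self.n_regulators
        )
        if planted + n_low > self.n_genes:
            raise ValueError(
                f"planted genes ({planted}) plus low-expressed genes ({n_low}) "
                f"exceed n_genes ({self.n_genes})"
            )
        if self.n_regulators > len(self.module_sizes):
            raise ValueError("cannot plant more regulators than modules")
        if not 0 < self.diff_hub_cor <= 1:
            raise ValueError("diff_hub_cor must lie in (0, 1]")


@dataclass
class PlantedTruth:
    """Ground truth of a synthetic study, used only for recovery scoring."""

    module_of_gene: dict[str, str]  # gene -> "M1".."Mk" or "background"
    latent_factors: pd.DataFrame  # modules x samples
    trait_targets: dict[str, str]  # module -> trait name
    diff_hub_genes: list[str]
    lean_hub_genes: list[str]
    regulator_of_cluster: dict[str, str]  # regulator gene -> module
    #: per regulator-driven module, sample ids on the "high" side of the split
    sample_partitions: dict[str, list[str]]
    #: noiseless log2-expression matrix (before count sampling)
    latent_log_expression: pd.DataFrame


@dataclass
class SyntheticStudy:
    counts: pd.DataFrame  # genes x samples, non-negative integers
    phenotypes: pd.DataFrame  # samples x (group, gender, traits...)
    gene_lengths: pd.Series  # gene -> bp
    gene_sets: dict[str, list[str]]
    candidate_regulators: list[str]
    truth: PlantedTruth


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    """Negative binomial with mean mu and variance mu + phi*mu^2."""
    if phi < 1e-12:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / phi, scale=mu * phi)
    return rng.poisson(lam)


def simulate_study(config: SimulationConfig) -> SyntheticStudy:
    """Generate a complete synthetic study with planted ground truth.

    Gene layout (deterministic given the config): module genes first, then
    the obese-only hub block, then regulator genes, then background genes of
    which a fraction are simulated at near-zero expression.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_per = config.n_samples_per_group
    n_samples = n_per * len(GROUPS)
    sample_ids = [f"S{i + 1:02d}" for i in range(n_samples)]
    group = np.repeat(GROUPS, n_per)
    # balanced gender within each group
    gender = np.concatenate([np.resize(["F", "M"], n_per) for _ in GROUPS])
    group_code = np.repeat([-1.0, 0.0, 1.0], n_per)
    obese = (group == "obese").astype(float)

    n_modules = len(config.module_sizes)
    module_names = [f"M{m + 1}" for m in range(n_modules)]
    gene_ids = [f"G{i + 1:05d}" for i in range(config.n_genes)]

    # ---- latent factors and sample partitions -------------------------------
    # modules 2..(n_regulators+1) are regulator-driven: their factor is a
    # noisy binary sample partition so the cluster's sample tree has a clean
    # root split for the regulator to explain.  Module 1 carries the obesity
    # index and uses a monotone group gradient.
    factors = np.empty((n_modules, n_samples))
    partitions: dict[str, list[str]] = {}
    regulator_modules = module_names[1 : 1 + config.n_regulators]
    for m, name in enumerate(module_names):
        if name in regulator_modules:
            # balanced random sample split, independent of the group design
            # so regulator-driven modules stay distinguishable from the
            # trait-gradient module
            z = np.zeros(n_samples)
            half = rng.permutation(n_samples)[: n_samples // 2]
            z[half] = 1.0
            partitions[name] = [s for s, zi in zip(sample_ids, z) if zi == 1.0]
            raw = (z - z.mean()) + config.partition_noise_sd * rng.standard_normal(n_samples)
        elif m == 0:
            raw = group_code + 0.5 * rng.standard_normal(n_samples)
        else:
            raw = rng.standard_normal(n_samples)
        factors[m] = (raw - raw.mean()) / raw.std()

    # ---- traits -------------------------------------------------------------
    trait_targets = {
        name: DEFAULT_TRAITS[m % len(DEFAULT_TRAITS)] for m, name in enumerate(module_names)
    }
    traits = pd.DataFrame(index=sample_ids)
    used: dict[str, np.ndarray] = {}
    for m, name in enumerate(module_names):
        tname = trait_targets[name]
        if tname in used:
            continue  # first module targeting a trait wins
        rho = config.module_trait_cor[m]
        raw = rho * factors[m] + math.sqrt(max(0.0, 1 - rho**2)) * rng.standard_normal(n_samples)
        used[tname] = raw
    for tname in DEFAULT_TRAITS:  # any trait not claimed by a module is pure noise
        if tname not in used:
            used[tname] = rng.standard_normal(n_samples)
        loc, scale = _TRAIT_UNITS[tname]
        traits[tname] = loc + scale * used[tname]

    phenotypes = pd.DataFrame({"group": group, "gender": gender}, index=sample_ids)
    phenotypes = pd.concat([phenotypes, traits], axis=1)
    phenotypes.index.name = "sample_id"

    # ---- gene-wise log2 signal ---------------------------------------------
    n_low = int(round(config.frac_low_expressed * config.n_genes))
    signal = np.empty((config.n_genes, n_samples))
    module_of_gene = {}
    pos = 0

    # counting adds roughly (1/mu + phi)/ln(2)^2 of variance on the log2
    # scale; planted latent correlations are inflated so the correlation
    # observed in the count-derived expression matches the configured target
    count_var = (2.0 ** -config.mean_log_expression + config.nb_dispersion) / math.log(2) ** 2

    def _latent_cor(target: float, sd: float) -> float:
        # never compensate past 0.98 — except that an exact target (e.g. the
        # deterministic w = 1 limit) is preserved as-is
        return min(max(0.98, target), target * (sd**2 + count_var) / sd**2)

    w = _latent_cor(config.within_module_cor, config.expression_sd)
    for m, (name, size) in enumerate(zip(module_names, config.module_sizes)):
        # per-gene loadings spread around sqrt(w) give each module a hub
        # spectrum (high-kME core, weaker periphery) like real modules while
        # keeping the mean pairwise correlation at w = E[load]^2
        delta = min(0.15, 1 - math.sqrt(w), math.sqrt(w))
        load = rng.uniform(math.sqrt(w) - delta, math.sqrt(w) + delta, size)[:, None]
        noise = rng.standard_normal((size, n_samples))
        signal[pos : pos + size] = config.expression_sd * (
            load * factors[m] + np.sqrt(1 - load**2) * noise
        )
        for g in gene_ids[pos : pos + size]:
            module_of_gene[g] = name
        pos += size

    # obese-only hub block: correlated among obese samples only, plus a mean
    # shift so the genes are also differentially expressed
    wh = _latent_cor(config.diff_hub_cor, config.hub_expression_sd)
    hub_genes = gene_ids[pos : pos + config.n_diff_hubs]
    lean_hub_genes = gene_ids[
        pos + config.n_diff_hubs : pos + config.n_diff_hubs + config.n_lean_hubs
    ]
    lean = (group == "lean").astype(float)
    for indicator, block in [(obese, hub_genes), (lean, lean_hub_genes)]:
        block_factor = rng.standard_normal(n_samples)
        for i, g in enumerate(block):
            noise = rng.standard_normal(n_samples)
            x = math.sqrt(1 - wh) * noise
            x = x + math.sqrt(wh) * block_factor * indicator  # zero loading elsewhere
            signal[pos] = config.hub_expression_sd * x + config.diff_hub_shift * indicator
            module_of_gene[g] = "background"
            pos += 1

    # planted regulators: monotone transform of the partition indicator + noise
    regulator_genes = gene_ids[pos : pos + config.n_regulators]
    regulator_of_cluster = {}
    for i, mod in enumerate(regulator_modules):
        z = np.isin(sample_ids, partitions[mod]).astype(float)
        signal[pos + i] = config.regulator_effect * (
            z - z.mean()
        ) + config.regulator_noise_sd * rng.standard_normal(n_samples)
        regulator_of_cluster[regulator_genes[i]] = mod
        module_of_gene[regulator_genes[i]] = "background"
    pos += config.n_regulators

    # background (including the low-expressed tail): weak, heterogeneous
    # loadings on a few shared global factors plus idiosyncratic noise
    n_bg = config.n_genes - pos
    if config.n_global_factors > 0 and n_bg > 0:
        gfac = rng.standard_normal((config.n_global_factors, n_samples))
        if n_modules:  # keep global variation orthogonal to the planted biology
            q, _ = np.linalg.qr(factors.T)
            gfac = gfac - (gfac @ q) @ q.T
            gfac = (gfac - gfac.mean(axis=1, keepdims=True)) / gfac.std(axis=1, keepdims=True)
        which = rng.integers(0, config.n_global_factors, n_bg)
        u = rng.uniform(0, config.background_loading_max, n_bg)[:, None]
        bg = u * gfac[which] + np.sqrt(1 - u**2) * rng.standard_normal((n_bg, n_samples))
    else:
        bg = rng.standard_normal((n_bg, n_samples))
    signal[pos:] = config.background_sd * bg
    for g in gene_ids[pos:]:
        module_of_gene[g] = "background"

    # ---- baselines, gender effect, counts ----------------------------------
    baseline = rng.uniform(
        config.mean_log_expression - 1.5, config.mean_log_expression + 1.5, config.n_genes
    )
    n_hk = int(round(config.frac_housekeeping * config.n_genes))
    n_hk = min(n_hk, max(0, n_bg - n_low))
    if n_hk:  # high-abundance background tail stabilizing the library mass
        hk_lo = config.n_genes - n_low - n_hk
        baseline[hk_lo : hk_lo + n_hk] = rng.uniform(
            config.mean_log_expression + 6, config.mean_log_expression + 8, n_hk
        )
    if n_low:
        baseline[config.n_genes - n_low :] = rng.uniform(0.5, 1.5, n_low)
    gender_eff = config.gender_effect_sd * rng.standard_normal(config.n_genes)
    male = (gender == "M").astype(float)

    log2_mu = baseline[:, None] + signal + gender_eff[:, None] * male[None, :]
    counts = _nb_counts(rng, np.exp2(log2_mu), config.nb_dispersion)
    counts = pd.DataFrame(counts, index=gene_ids, columns=sample_ids)
    counts.index.name = "gene_id"

    # ---- gene lengths: log-uniform, with module genes biased longer so the
    # enrichment stage has a length bias to correct
    log_len = rng.uniform(math.log10(200), math.log10(100_000), config.n_genes)
    in_module = np.array([module_of_gene[g] != "background" for g in gene_ids])
    log_len = np.clip(log_len + 0.4 * in_module, math.log10(200), math.log10(100_000))
    gene_lengths = pd.Series(
        np.maximum(200, np.round(10**log_len)).astype(int), index=gene_ids, name="length"
    )
    gene_lengths.index.name = "gene_id"

    # ---- gene sets: one matched term per module plus random background terms
    expressed = gene_ids[: config.n_genes - n_low]
    gene_sets: dict[str, list[str]] = {}
    for m, (name, size) in enumerate(zip(module_names, config.module_sizes)):
        members = list(counts.index[sum(config.module_sizes[:m]) : sum(config.module_sizes[: m + 1])])
        keep = rng.permutation(len(members))[: int(0.8 * len(members))]
        extra = rng.choice(len(expressed), size=min(20, len(expressed)), replace=False)
        term = sorted({members[i] for i in keep} | {expressed[i] for i in extra})
        gene_sets[f"TERM_{name}"] = term
    for t in range(config.n_background_terms):
        size = min(int(rng.integers(20, 150)), len(expressed))
        idx = rng.choice(len(expressed), size=size, replace=False)
        gene_sets[f"TERM_RND{t + 1:02d}"] = sorted(expressed[i] for i in idx)

    # ---- candidate regulators: planted ones plus background decoys ---------
    n_decoys = max(0, config.n_candidate_regulators - config.n_regulators)
    bg_pool = [g for g in expressed if module_of_gene[g] == "background" and g not in regulator_genes]
    if n_decoys > len(bg_pool):
        raise ValueError("not enough background genes for the requested candidate list")
    decoys = [bg_pool[i] for i in rng.choice(len(bg_pool), size=n_decoys, replace=False)]
    candidate_regulators = sorted(set(regulator_genes) | set(decoys))

    truth = PlantedTruth(
        module_of_gene=module_of_gene,
        latent_factors=pd.DataFrame(factors, index=module_names, columns=sample_ids),
        trait_targets=trait_targets,
        diff_hub_genes=list(hub_genes),
        lean_hub_genes=list(lean_hub_genes),
        regulator_of_cluster=regulator_of_cluster,
        sample_partitions=partitions,
        latent_log_expression=pd.DataFrame(log2_mu, index=gene_ids, columns=sample_ids),
    )
    return SyntheticStudy(
        counts=counts,
        phenotypes=phenotypes,
        gene_lengths=gene_lengths,
        gene_sets=gene_sets,
        candidate_regulators=candidate_regulators,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def write_gmt(gene_sets: dict[str, list[str]], path: str | Path) -> None:
    """Write gene sets in the standard GMT format (term, description, members)."""
    with open(path, "w") as fh:
        for term in gene_sets:
            fh.write("\t".join([term, "na", *gene_sets[term]]) + "\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    from gseapy.parser import read_gmt as _read_gmt

    return _read_gmt(str(path))


def write_study(study: SyntheticStudy, directory: str | Path) -> list[Path]:
    """Persist a study as plain-text files; the round trip is exact.

    Emits counts.tsv, phenotypes.csv, gene_lengths.tsv, gene_sets.gmt,
    regulators.txt, truth.json and latent_log_expression.tsv.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    t = study.truth
    files = {
        "counts.tsv": lambda p: study.counts.to_csv(p, sep="\t"),
        "phenotypes.csv": lambda p: study.phenotypes.to_csv(p),
        "gene_lengths.tsv": lambda p: study.gene_lengths.to_csv(p, sep="\t"),
        "gene_sets.gmt": lambda p: write_gmt(study.gene_sets, p),
        "regulators.txt": lambda p: p.write_text(
            "".join(f"{g}\n" for g in study.candidate_regulators)
        ),
        "latent_log_expression.tsv": lambda p: t.latent_log_expression.to_csv(p, sep="\t"),
        "truth.json": lambda p: p.write_text(
            json.dumps(
                {
                    "module_of_gene": t.module_of_gene,
                    "latent_factors": {
                        m: list(t.latent_factors.loc[m]) for m in t.latent_factors.index
                    },
                    "sample_ids": list(t.latent_factors.columns),
                    "trait_targets": t.trait_targets,
                    "diff_hub_genes": t.diff_hub_genes,
                    "lean_hub_genes": t.lean_hub_genes,
                    "regulator_of_cluster": t.regulator_of_cluster,
                    "sample_partitions": t.sample_partitions,
                },
                indent=1,
                sort_keys=True,
            )
        ),
    }
    written = []
    for name, writer in files.items():
        p = directory / name
        writer(p)
        written.append(p)
    return written


def read_study(directory: str | Path) -> SyntheticStudy:
    """Load a study written by :func:`write_study`."""
    directory = Path(directory)
    counts = pd.read_csv(directory / "counts.tsv", sep="\t", index_col=0)
    # round_trip parsing keeps floats ulp-exact so re-writing is byte-stable
    phenotypes = pd.read_csv(
        directory / "phenotypes.csv", index_col=0, float_precision="round_trip"
    )
    gene_lengths = pd.read_csv(directory / "gene_lengths.tsv", sep="\t", index_col=0)["length"]
    gene_sets = read_gmt(directory / "gene_sets.gmt")
    regulators = (directory / "regulators.txt").read_text().split()
    raw = json.loads((directory / "truth.json").read_text())
    latent = pd.read_csv(
        directory / "latent_log_expression.tsv", sep="\t", index_col=0,
        float_precision="round_trip",
    )
    truth = PlantedTruth(
        module_of_gene=raw["module_of_gene"],
        latent_factors=pd.DataFrame(raw["latent_factors"], index=raw["sample_ids"]).T,
        trait_targets=raw["trait_targets"],
        diff_hub_genes=raw["diff_hub_genes"],
        lean_hub_genes=raw.get("lean_hub_genes", []),
        regulator_of_cluster=raw["regulator_of_cluster"],
        sample_partitions=raw["sample_partitions"],
        latent_log_expression=latent,
    )
    return SyntheticStudy(
        counts=counts,
        phenotypes=phenotypes,
        gene_lengths=gene_lengths,
        gene_sets=gene_sets,
        candidate_regulators=regulators,
        truth=truth,
    )
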