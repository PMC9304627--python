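"""Synthetic paired-cohort generator with planted ground truth.

Emulates the statistical structure of a case-control gut-microbiome study:
~20 control subjects sampled once and ~19 patients sampled at baseline (T0)
and after treatment (T1), with

* compositional counts drawn by a logistic-normal-multinomial scheme —
  per-sample latent Gaussian log-abundances with a planted block-correlation
  covariance, softmax to a composition, multinomial read sampling at a
  random depth;
* planted co-occurrence modules: groups of taxa sharing a latent pairwise
  correlation, the ground truth against which network recovery is scored;
* a baseline diversity deficit in patients (the patient latent mean is
  sharpened, concentrating the composition) partially undone at T1 by a
  per-subject convex blend toward the control latent state;
* clinical/metabolite variables generated as noisy linear functions of the
  latent mean of a linked module, optionally with a persistent group shift
  (e.g. a depressed propionic-acid level in patients at both timepoints).

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from .io import CountTable, TaxonomyMap, validate_metadata

__all__ = [
    "PlantedModule",
    "VariableSpec",
    "CohortSpec",
    "PlantedTruth",
    "CohortData",
    "generate_cohort",
    "generate_tree",
]


@dataclass
class PlantedModule:
    """A group of taxa sharing a latent pairwise correlation."""

    members: list[str]
    rho: float = 0.85

    def __post_init__(self) -> None:
        if not -1 < self.rho < 1:
            raise ValueError("module correlation must lie in (-1, 1)")


@dataclass
class VariableSpec:
    """A clinical or metabolite variable.

    The variable equals ``base_mean * (1 + era_shift)`` in patients (both
    timepoints) or ``base_mean`` in controls, plus ``sign * strength`` times
    the standardised latent mean of the linked module (if any), plus Gaussian
    noise so the marginal SD is ``base_sd``.
    """

    name: str
    kind: str = "clinical"  # or "metabolite"
    module: int | None = None
    sign: int = 1
    strength: float = 0.0
    base_mean: float = 0.0
    base_sd: float = 1.0
    era_shift: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.strength < 1:
            raise ValueError("coupling strength must lie in [0, 1)")
        if self.sign not in (-1, 1):
            raise ValueError("sign must be +1 or -1")


def _default_modules(n_taxa: int) -> list[PlantedModule]:
    names = [f"OTU_{i:04d}" for i in range(n_taxa)]
    return [
        PlantedModule(members=names[0:6], rho=0.85),
        PlantedModule(members=names[6:11], rho=0.75),
    ]


def _default_variables() -> list[VariableSpec]:
    return [
        VariableSpec("DAS28", kind="clinical", module=0, sign=-1, strength=0.6,
                     base_mean=3.5, base_sd=1.2),
        VariableSpec("Treg_pct", kind="clinical", module=1, sign=1, strength=0.6,
                     base_mean=5.0, base_sd=1.5),
        VariableSpec("propionic_acid", kind="metabolite", module=0, sign=1,
                     strength=0.6, base_mean=10.0, base_sd=2.5, era_shift=-0.4),
    ]


@dataclass
class CohortSpec:
    """Design of a synthetic paired cohort.

    Defaults encode the study design being emulated: 20 controls, 19
    patients with two timepoints, sequencing depths drawn uniformly in
    8,000-20,000 so a 6,000-read rarefaction is exercised, a baseline
    diversity deficit in patients 70% restored at T1, and one metabolite
    depressed ~40% in patients at both timepoints.
    """

    n_ctrl: int = 20
    n_era: int = 19
    n_taxa: int = 150
    modules: list[PlantedModule] | None = None
    variables: list[VariableSpec] | None = None
    diversity_deficit: float = 0.5  # latent-mean sharpening factor for ERA-T0
    restoration: float = 0.7  # convex weight toward the control state at T1
    mu_sd: float = 1.5  # spread of baseline log-abundance means
    module_mu: float = 2.0  # elevated log-mean of planted-module taxa
    sigma: float = 1.0  # latent log-abundance SD per taxon
    depth_range: tuple[int, int] = (8000, 20000)
    era_log_shift: dict[str, float] = field(default_factory=dict)  # taxon -> log-mean shift in patients

    def __post_init__(self) -> None:
        if self.n_ctrl < 2 or self.n_era < 2:
            raise ValueError("group sizes must be >= 2")
        if self.modules is None:
            self.modules = _default_modules(self.n_taxa)
        if self.variables is None:
            self.variables = _default_variables()
        seen: set[str] = set()
        for mod in self.modules:
            if seen & set(mod.members):
                raise ValueError("planted modules must be disjoint")
            seen |= set(mod.members)
        if not 0 <= self.restoration <= 1:
            raise ValueError("restoration must lie in [0, 1]")

    @classmethod
    def null(cls, **kwargs) -> "CohortSpec":
        """Zero-effect spec: no planted correlation, no group differences —
        all three strata are exchangeable."""
        defaults = dict(
            modules=[],
            variables=[
                VariableSpec("DAS28", base_mean=3.5, base_sd=1.2),
                VariableSpec("Treg_pct", base_mean=5.0, base_sd=1.5),
                VariableSpec("propionic_acid", kind="metabolite",
                             base_mean=10.0, base_sd=2.5),
            ],
            diversity_deficit=0.0,
            restoration=0.0,
        )
        defaults.update(kwargs)
        return cls(**defaults)

    @property
    def taxon_ids(self) -> list[str]:
        return [f"OTU_{i:04d}" for i in range(self.n_taxa)]


@dataclass
class PlantedTruth:
    """Ground truth of a generated cohort.

    ``latent_correlation`` is the taxa x taxa latent correlation matrix
    (shared by all strata); ``species_pairs`` lists every planted within-
    module taxon pair and ``variable_pairs`` every planted (taxon, variable,
    sign) association.
    """

    latent_correlation: pd.DataFrame
    species_pairs: list[tuple[str, str]]
    variable_pairs: list[tuple[str, str, int]]

    def __post_init__(self) -> None:
        r = self.latent_correlation.to_numpy()
        if not np.allclose(r, r.T):
            raise ValueError("latent correlation must be symmetric")
        if not np.allclose(np.diag(r), 1.0):
            raise ValueError("latent correlation must have unit diagonal")
        if np.linalg.eigvalsh(r).min() < -1e-8:
            raise ValueError("latent correlation must be positive semidefinite")


@dataclass
class CohortData:
    table: CountTable
    taxonomy: TaxonomyMap
    meta: pd.DataFrame
    tree: TreeNode
    truth: PlantedTruth


def _correlation_matrix(spec: CohortSpec) -> pd.DataFrame:
    taxa = spec.taxon_ids
    r = np.eye(spec.n_taxa)
    pos = {t: i for i, t in enumerate(taxa)}
    for mod in spec.modules:
        idx = [pos[m] for m in mod.members]
        for a in idx:
            for b in idx:
                if a != b:
                    r[a, b] = mod.rho
    if np.linalg.eigvalsh(r).min() < -1e-8:
        raise ValueError("requested latent covariance is not positive semidefinite")
    return pd.DataFrame(r, index=taxa, columns=taxa)


def _taxonomy(spec: CohortSpec) -> TaxonomyMap:
    rows = []
    for i, taxon in enumerate(spec.taxon_ids):
        rows.append(
            {"taxon_id": taxon, "genus": f"g__G{i // 2:03d}", "species": f"s__S{i:04d}"}
        )
    return TaxonomyMap(pd.DataFrame(rows).set_index("taxon_id"))


def generate_cohort(spec: CohortSpec, seed: int) -> CohortData:
    """Draw one cohort from the spec; bit-reproducible given ``seed``."""
    rng = np.random.default_rng(seed)
    taxa = spec.taxon_ids
    n_taxa = spec.n_taxa
    corr = _correlation_matrix(spec)
    chol = np.linalg.cholesky(corr.to_numpy() + 1e-10 * np.eye(n_taxa))

    mu_ctrl = rng.normal(0.0, spec.mu_sd, size=n_taxa)
    module_members = [m for mod in spec.modules for m in mod.members]
    pos = {t: i for i, t in enumerate(taxa)}
    for m in module_members:
        mu_ctrl[pos[m]] = spec.module_mu
    # sharpening the latent mean concentrates the softmax composition,
    # lowering expected Shannon/Simpson diversity for patients at baseline
    mu_era = (1.0 + spec.diversity_deficit) * mu_ctrl
    for taxon, shift in spec.era_log_shift.items():
        mu_era[pos[taxon]] += shift

    def latent(mu: np.ndarray) -> np.ndarray:
        return mu + spec.sigma * (chol @ rng.standard_normal(n_taxa))

    sample_ids, metas, latents = [], [], []

    def add_sample(sid, group, timepoint, subject, z):
        sample_ids.append(sid)
        metas.append({"group": group, "timepoint": timepoint, "subject_id": subject})
        latents.append(z)

    for i in range(spec.n_ctrl):
        add_sample(f"CTRL_{i:02d}", "CTRL", "T0", f"C{i:02d}", latent(mu_ctrl))
    for i in range(spec.n_era):
        subj = f"E{i:02d}"
        z0 = latent(mu_era)
        z1 = (1.0 - spec.restoration) * z0 + spec.restoration * latent(mu_ctrl)
        add_sample(f"ERA_{i:02d}_T0", "ERA", "T0", subj, z0)
        add_sample(f"ERA_{i:02d}_T1", "ERA", "T1", subj, z1)

    latents_arr = np.asarray(latents)
    comp = np.exp(latents_arr - latents_arr.max(axis=1, keepdims=True))
    comp /= comp.sum(axis=1, keepdims=True)
    depths = rng.integers(spec.depth_range[0], spec.depth_range[1] + 1, len(sample_ids))
    counts = np.stack([rng.multinomial(d, p) for d, p in zip(depths, comp)])
    table = CountTable(pd.DataFrame(counts, index=sample_ids, columns=taxa))

    meta = pd.DataFrame(metas, index=sample_ids)
    for var in spec.variables:
        if var.module is not None and var.module < len(spec.modules):
            members = [pos[m] for m in spec.modules[var.module].members]
            signal = latents_arr[:, members].mean(axis=1)
            sd = signal.std()
            signal = (signal - signal.mean()) / (sd if sd > 0 else 1.0)
        else:
            signal = np.zeros(len(sample_ids))
        noise = rng.standard_normal(len(sample_ids))
        zscore = var.sign * var.strength * signal + np.sqrt(1 - var.strength**2) * noise
        is_era = meta["group"].to_numpy() == "ERA"
        shift = np.where(is_era, 1.0 + var.era_shift, 1.0)
        meta[var.name] = var.base_mean * shift + var.base_sd * zscore
    meta = validate_metadata(meta)

    species_pairs = [
        (a, b)
        for mod in spec.modules
        for i, a in enumerate(mod.members)
        for b in mod.members[i + 1 :]
    ]
    variable_pairs = [
        (m, var.name, var.sign)
        for var in spec.variables
        if var.module is not None and var.module < len(spec.modules) and var.strength > 0
        for m in spec.modules[var.module].members
    ]
    truth = PlantedTruth(
        latent_correlation=corr,
        species_pairs=species_pairs,
        variable_pairs=variable_pairs,
    )
    tree = generate_tree(taxa, seed=int(rng.integers(0, 2**31 - 1)))
    return CohortData(table=table, taxonomy=_taxonomy(spec), meta=meta, tree=tree, truth=truth)


def generate_tree(taxa, seed: int) -> TreeNode:
    """Random coalescent-style rooted tree over the given taxa.

    Lineages are merged pairwise at exponentially distributed waiting times,
    giving an ultrametric binary tree with strictly positive branch lengths.
    """
    taxa = list(taxa)
    if len(taxa) < 2:
        raise ValueError("need at least 2 taxa to build a tree")
    rng = np.random.default_rng(seed)
    nodes = [TreeNode(name=t, length=None) for t in taxa]
    heights = [0.0] * len(nodes)
    height = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        height += rng.exponential(1.0 / (k * (k - 1) / 2.0))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length = height - heights[i]
        nodes[j].length = height - heights[j]
        nodes[i] = parent
        heights[i] = height
        del nodes[j], heights[j]
    root = nodes[0]
    root.length = 0.0
    return root
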