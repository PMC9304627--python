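"""End-to-end orchestration: filter -> rarefy -> diversity -> differential
abundance -> per-stratum co-occurrence networks, with a JSON manifest that
records every threshold, seed and dropped sample so any table can be
reproduced from the config alone."""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .da import compare_taxa, select_abundant_taxa
from .diversity import (
    alpha_diversity,
    bray_curtis,
    pc1_paired_test,
    pcoa,
    permanova,
    unweighted_unifrac,
)
from .io import (
    CountTable,
    aggregate_by_rank,
    filter_rare_otus,
    rarefy,
    read_count_table,
    read_metadata,
    read_taxonomy,
    read_tree,
    strata,
    to_relative_abundance,
    variable_columns,
)
from .network import build_network, detect_hubs, detect_modules, write_network
from .stats import mann_whitney_u

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed or a required upstream stage is disabled."""


@dataclass
class PipelineConfig:
    """All knobs of the pipeline in one place.

    The defaults are the analysis constants of the study design: rarefaction
    to 6,000 reads, rare-OTU removal (< 2 samples or < 10 reads), a 1%
    abundance screen for differential abundance, a 0.1% screen for network
    species, |rho| thresholds 0.6 / 0.5, bootstrap B = 1000 at alpha = 0.05
    and 1,000 PERMANOVA permutations.
    """

    count_table: str
    metadata: str
    out_dir: str
    taxonomy: str | None = None
    tree: str | None = None
    orientation: str = "samples"
    seed: int = 0
    min_samples: int = 2
    min_total: int = 10
    depth: int = 6000
    filter_before_rarefy: bool = True
    rank: str = "species"
    abundance_threshold: float = 0.01
    species_threshold: float = 0.001
    rho_species: float = 0.6
    rho_variable: float = 0.5
    alpha: float = 0.05
    n_boot: int = 1000
    n_perm: int = 1000
    metabolite_variables: list[str] = field(default_factory=list)
    stages: dict[str, bool] = field(
        default_factory=lambda: {
            "preprocess": True,
            "diversity": True,
            "daa": True,
            "network": True,
        }
    )


def _stage_seeds(seed: int) -> dict[str, int]:
    rng = np.random.default_rng(seed)
    return {
        name: int(rng.integers(0, 2**31 - 1))
        for name in ("rarefy", "permanova_bc", "permanova_uf", "network")
    }


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all enabled stages; returns the manifest (also written to disk)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(cfg.seed)
    manifest: dict = {
        "version": __version__,
        "config": asdict(cfg),
        "stage_seeds": seeds,
        "stages": {},
    }

    def log(stage: str, **info) -> None:
        manifest["stages"][stage] = info

    if not cfg.stages.get("preprocess", True):
        needed = [
            s for s in ("diversity", "daa", "network") if cfg.stages.get(s, True)
        ]
        if needed:
            raise PipelineError(
                f"stage(s) {needed} require stage 'preprocess', which is disabled"
            )
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        return manifest

    # ---- load + preprocess ------------------------------------------------
    try:
        table = read_count_table(cfg.count_table, orientation=cfg.orientation)
        meta = read_metadata(cfg.metadata)
        taxonomy = read_taxonomy(cfg.taxonomy) if cfg.taxonomy else None
        tree = read_tree(cfg.tree) if cfg.tree else None
    except Exception as exc:
        raise PipelineError(f"stage 'load' failed: {exc}") from exc
    meta = meta.loc[meta.index.intersection(table.sample_ids)]
    log("load", n_samples=table.shape[0], n_taxa=table.shape[1])

    try:
        if cfg.filter_before_rarefy:
            filtered = filter_rare_otus(table, cfg.min_samples, cfg.min_total)
            rare = rarefy(filtered, depth=cfg.depth, seed=seeds["rarefy"])
            table_r = rare.table
        else:
            rare = rarefy(table, depth=cfg.depth, seed=seeds["rarefy"])
            table_r = filter_rare_otus(rare.table, cfg.min_samples, cfg.min_total)
    except Exception as exc:
        raise PipelineError(f"stage 'preprocess' failed: {exc}") from exc
    meta = meta.loc[meta.index.intersection(table_r.sample_ids)]
    log(
        "preprocess",
        n_samples=table_r.shape[0],
        n_taxa=table_r.shape[1],
        dropped_samples=rare.dropped,
        depth=cfg.depth,
    )
    if taxonomy is not None and cfg.rank:
        table_rank = aggregate_by_rank(table_r, taxonomy, cfg.rank)
    else:
        table_rank = table_r
    rel = to_relative_abundance(table_rank)
    rel.to_csv(out / "relative_abundance.tsv", sep="\t")

    # ---- diversity --------------------------------------------------------
    if cfg.stages.get("diversity", True):
        try:
            alpha = alpha_diversity(table_r)
            alpha.to_csv(out / "alpha_diversity.tsv", sep="\t")
            groups = strata(meta)
            alpha_tests = []
            for left, right in (("CTRL", "ERA-T0"), ("CTRL", "ERA-T1")):
                if left not in groups or right not in groups:
                    continue
                for index_name in alpha.columns:
                    u, p = mann_whitney_u(
                        alpha.loc[alpha.index.intersection(groups[left]), index_name],
                        alpha.loc[alpha.index.intersection(groups[right]), index_name],
                    )
                    alpha_tests.append(
                        {"contrast": f"{left}_vs_{right}", "index": index_name,
                         "U": u, "p": p}
                    )
            pd.DataFrame(alpha_tests).to_csv(out / "alpha_tests.tsv", sep="\t", index=False)

            labels = pd.Series(
                [
                    f"{g}-{t}" if g == "ERA" else g
                    for g, t in zip(meta["group"], meta["timepoint"])
                ],
                index=meta.index,
            )
            beta_results = {}
            dm_bc = bray_curtis(table_r)
            dm_bc.write(str(out / "bray_curtis.tsv"))
            dms = {"bray_curtis": (dm_bc, seeds["permanova_bc"])}
            if tree is not None:
                dm_uf = unweighted_unifrac(table_r, tree)
                dm_uf.write(str(out / "unweighted_unifrac.tsv"))
                dms["unweighted_unifrac"] = (dm_uf, seeds["permanova_uf"])
            for name, (dm, seed) in dms.items():
                ids = [s for s in dm.ids if s in labels.index]
                dm_f = dm.filter(ids)
                ctrl_t0 = [s for s in ids if labels[s] in ("CTRL", "ERA-T0")]
                res = permanova(
                    dm_f.filter(ctrl_t0), labels[ctrl_t0],
                    n_perm=cfg.n_perm, seed=seed,
                )
                ordn = pcoa(dm_f)
                ordn.coordinates.to_csv(out / f"pcoa_{name}.tsv", sep="\t")
                try:
                    w, p_paired = pc1_paired_test(ordn, meta)
                except ValueError:
                    w, p_paired = np.nan, np.nan
                beta_results[name] = {
                    "permanova_F_CTRL_vs_ERA-T0": res.pseudo_f,
                    "permanova_p_CTRL_vs_ERA-T0": res.p_value,
                    "n_permutations": res.n_permutations,
                    "pc1_paired_W": w,
                    "pc1_paired_p": p_paired,
                    "pct_var_PC1": float(ordn.proportion_explained[0]),
                }
            with open(out / "beta_tests.json", "w") as fh:
                json.dump(beta_results, fh, indent=2)
            log("diversity", beta=beta_results)
        except Exception as exc:
            raise PipelineError(f"stage 'diversity' failed: {exc}") from exc

    # ---- differential abundance ------------------------------------------
    if cfg.stages.get("daa", True):
        try:
            taxa = select_abundant_taxa(rel, meta, threshold=cfg.abundance_threshold)
            daa = compare_taxa(rel, meta, taxa, rank=cfg.rank)
            daa.to_csv(out / "differential_abundance.tsv", sep="\t", index=False)
            log("daa", n_taxa_screened=len(taxa))
        except Exception as exc:
            raise PipelineError(f"stage 'daa' failed: {exc}") from exc

    # ---- networks ---------------------------------------------------------
    if cfg.stages.get("network", True):
        try:
            vars_ = variable_columns(meta)
            variables = meta[vars_] if vars_ else None
            kinds = {
                v: ("metabolite" if v in cfg.metabolite_variables else "clinical")
                for v in vars_
            }
            rng = np.random.default_rng(seeds["network"])
            topo = {}
            for group in strata(meta):
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = build_network(
                        rel, meta, group,
                        variables=variables, variable_kinds=kinds,
                        species_threshold=cfg.species_threshold,
                        rho_species=cfg.rho_species, rho_variable=cfg.rho_variable,
                        alpha=cfg.alpha, n_boot=cfg.n_boot,
                        seed=int(rng.integers(0, 2**31 - 1)),
                    )
                write_network(res.network, out / f"network_{group}")
                topo[group] = res.topology().printed()
                mods = detect_modules(res.network)
                pd.DataFrame(
                    [
                        {"module": label, "node": node}
                        for label, members in mods.modules.items()
                        for node in sorted(members)
                    ]
                ).to_csv(out / f"modules_{group}.tsv", sep="\t", index=False)
                hub = detect_hubs(res.network)
                hub.degrees.rename("degree").to_frame().assign(
                    hub=lambda df: df.index.isin(hub.hubs)
                ).to_csv(out / f"hubs_{group}.tsv", sep="\t")
            with open(out / "topology.json", "w") as fh:
                json.dump(topo, fh, indent=2)
            log("network", topology=topo)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage 'network' failed: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
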