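"""End-to-end orchestration: simulate -> popgen -> quantgen -> matrices ->
Q_ST/F_ST -> tree, from a single seeded configuration.

Every stochastic stage derives its stream from the one run seed, so a rerun
with an identical config is bit-identical; each output table carries the
config hash in a leading comment line and the run manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import markers, matrices, phylo, quantgen, qstfst
from .distmat import DistanceMatrix
from .geo import climate_distance_matrices, geographic_distance_matrix
from .simulate import (GardenSimConfig, MarkerSimConfig, simulate_common_garden,
                       simulate_geography_climate, simulate_markers)

__all__ = ["RunConfig", "run_pipeline", "report"]

ALL_STAGES = ("simulate", "popgen", "quantgen", "matrices", "qstfst", "tree")


@dataclass
class RunConfig:
    """Pipeline settings; defaults give a small but complete smoke run."""

    seed: int = 0
    out_dir: str = "run"
    stages: tuple = ALL_STAGES
    n_pops: int = 8
    n_loci: int = 15
    n_per_pop: int = 15
    target_fst: float = 0.086
    n_prov: int = 8
    families_per_prov: int | list = 5
    n_blocks: int = 5
    n_per_family_block: int = 3
    var_provenance: float = 0.5
    var_family: float = 0.0625
    var_residual: float = 1.0
    trait: str = "HEIT"
    year: int = 1
    n_perm: int = 999
    n_boot: int = 200
    n_resamples: int = 2000
    hwe_method: str = "chi2"
    hwe_n_mc: int = 10_000

    def __post_init__(self):
        self.stages = tuple(self.stages)
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.n_prov > self.n_pops:
            raise ValueError("n_prov cannot exceed n_pops (provenances are a "
                             "subset of the marker populations)")

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls(**yaml.safe_load(fh))

    def as_dict(self) -> dict:
        d = asdict(self)
        d["stages"] = list(self.stages)
        return d

    @property
    def config_hash(self) -> str:
        # out_dir does not affect results: identical analyses hash equal
        d = {k: v for k, v in self.as_dict().items() if k != "out_dir"}
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write(df: pd.DataFrame, path: Path, tag: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# config_hash={tag}\n")
        df.to_csv(fh, index=False)


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the requested stages in dependency order; returns the run dir."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tag = cfg.config_hash
    log: list[str] = [f"config_hash={tag}", f"seed={cfg.seed}"]
    cfg.to_yaml(out / "config.yaml")
    want = set(cfg.stages)

    def need(stage, *deps):
        missing = [d for d in deps if d not in want]
        if missing:
            raise ValueError(f"stage {stage!r} requires {missing} in this run")

    gt = tt = meta = climate = None
    if "simulate" in want:
        mcfg = MarkerSimConfig(n_pops=cfg.n_pops, n_loci=cfg.n_loci,
                               n_per_pop=cfg.n_per_pop,
                               target_fst=cfg.target_fst, seed=cfg.seed)
        gt, truth = simulate_markers(mcfg)
        gcfg = GardenSimConfig(
            n_prov=cfg.n_prov, families_per_prov=cfg.families_per_prov,
            n_blocks=cfg.n_blocks, n_per_family_block=cfg.n_per_family_block,
            var_provenance=cfg.var_provenance, var_family=cfg.var_family,
            var_residual=cfg.var_residual, trait=cfg.trait, year=cfg.year,
            seed=cfg.seed)
        tt, gtruth = simulate_common_garden(gcfg)
        # garden provenances are the first n_prov marker populations
        pops = gt.population_labels[:cfg.n_prov]
        tt["provenance"] = tt["provenance"].map(
            dict(zip([f"prov{j + 1:02d}" for j in range(cfg.n_prov)], pops)))
        meta, climate = simulate_geography_climate(cfg.n_pops, seed=cfg.seed)
        gt.write_genalex(out / "genotypes.csv")
        _write(tt, out / "traits.csv", tag)
        _write(climate, out / "climate.csv", tag)
        pd.DataFrame([m.__dict__ for m in meta]).to_csv(
            out / "population_meta.csv", index=False)
        truth.var_provenance = gtruth.var_provenance
        truth.var_family = gtruth.var_family
        truth.var_residual = gtruth.var_residual
        truth.true_qst = gtruth.true_qst
        truth.block_effects = gtruth.block_effects
        truth.to_yaml(out / "truth.yaml")
        log.append(f"simulate: {len(gt.individuals)} genotypes, "
                   f"{len(tt)} trait observations")

    theta_dm = nei_dm = None
    if "popgen" in want:
        need("popgen", "simulate")
        div = markers.diversity_stats(gt)
        _write(div.per_population, out / "diversity_per_population.csv", tag)
        _write(markers.aggregate_diversity(div.per_population).reset_index()
               .rename(columns={"index": "statistic"}),
               out / "diversity_means.csv", tag)
        hw = markers.hwe_tests(gt, method=cfg.hwe_method,
                               n_mc=max(cfg.hwe_n_mc, 1000), seed=cfg.seed)
        _write(hw, out / "hwe.csv", tag)
        g = markers.gst(gt)
        per_locus = g.per_locus.copy()
        _write(per_locus, out / "differentiation_by_locus.csv", tag)
        theta_dm = markers.pairwise_fst(gt)
        theta_dm.write_csv(out / "pairwise_fst.csv", header_comment=f"config_hash={tag}")
        nei_dm = markers.nei_distance(gt)
        nei_dm.write_csv(out / "nei_distance.csv", header_comment=f"config_hash={tag}")
        log.append(f"popgen: multilocus G_ST={g.multilocus_gst:.4f}, "
                   f"multilocus theta={markers.multilocus_theta(gt):.4f}")

    vc = None
    qst_mats = {}
    if "quantgen" in want:
        need("quantgen", "simulate")
        rows = []
        for (trait, year), _ in tt.groupby(["trait", "year"]):
            vc = quantgen.fit_varcomp(tt, trait, int(year))
            rows.append((trait, int(year), vc.sigma2_P, vc.sigma2_F,
                         vc.sigma2_E, vc.qst, vc.converged, vc.n_obs))
            qm = quantgen.pairwise_qst(tt, trait, int(year))
            qm.matrix.write_csv(out / f"qst_pairwise_{trait}{year}.csv",
                                header_comment=f"config_hash={tag}")
            qst_mats[(trait, int(year))] = qm.matrix
        _write(pd.DataFrame(rows, columns=["trait", "year", "sigma2_P",
                                           "sigma2_F", "sigma2_E", "qst",
                                           "converged", "n_obs"]),
               out / "variance_components.csv", tag)
        _write(quantgen.annual_qst_summary(tt), out / "qst_annual_summary.csv",
               tag)
        log.append(f"quantgen: global Q_ST={rows[-1][5]:.4f} "
                   f"({len(qst_mats)} trait-years)")

    if "matrices" in want:
        need("matrices", "simulate", "popgen", "quantgen")
        geo_dm = geographic_distance_matrix(meta)
        geo_dm.write_csv(out / "geo_distance.csv",
                         header_comment=f"config_hash={tag}")
        ibd = matrices.ibd_regression(theta_dm.clipped(), geo_dm,
                                      n_perm=cfg.n_perm, seed=cfg.seed)
        _write(pd.DataFrame([ibd.__dict__]), out / "ibd_regression.csv", tag)
        mres = matrices.mantel(theta_dm.clipped(), geo_dm, n_perm=cfg.n_perm,
                               seed=cfg.seed)
        _write(pd.DataFrame([mres.__dict__]), out / "mantel_fst_geo.csv", tag)
        preds = {"geography": geo_dm}
        for var, dmv in climate_distance_matrices(climate).items():
            preds[var] = dmv
        # align predictors to the provenance subset used for Q_ST
        sub_preds = {}
        for name, dmv in preds.items():
            labels = list(qst_mats.values())[0].labels
            idx = [dmv.labels.index(l) for l in labels]
            sub_preds[name] = DistanceMatrix(
                labels, dmv.values[np.ix_(idx, idx)], dmv.mask[np.ix_(idx, idx)])
        corr = matrices.qst_correlation_table(qst_mats, sub_preds,
                                              n_perm=cfg.n_perm, seed=cfg.seed)
        _write(corr, out / "qst_correlations.csv", tag)
        log.append(f"matrices: Mantel r={mres.r:.4f} (p={mres.p:.4f}, "
                   f"{mres.n_perm} perms); IBD b={ibd.b:.4g}")

    if "qstfst" in want:
        need("qstfst", "simulate", "quantgen")
        results = []
        gsub = gt.subset_populations(sorted(tt["provenance"].unique()))
        for (trait, year), _ in tt.groupby(["trait", "year"]):
            results.append(qstfst.qst_fst_test(tt, gsub, trait, int(year),
                                               n_resamples=cfg.n_resamples,
                                               seed=cfg.seed))
        _write(qstfst.qstfst_table(results), out / "qstfst_table.csv", tag)
        log.append(f"qstfst: {len(results)} trait-years, "
                   f"calls={[r.direction for r in results]}")

    if "tree" in want:
        need("tree", "simulate", "popgen")
        tree = phylo.bootstrap_support(gt, n_boot=cfg.n_boot, seed=cfg.seed)
        (out / "tree.nwk").write_text(phylo.write_newick(tree) + "\n",
                                      encoding="utf-8")
        log.append(f"tree: {len(tree.leaf_names)} leaves, "
                   f"{tree.n_boot_used} bootstrap replicates used")

    manifest = {
        "config_hash": tag,
        "stages": list(cfg.stages),
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True),
                                       encoding="utf-8")
    (out / "log.txt").write_text("\n".join(log) + "\n", encoding="utf-8")
    return out


_SECTIONS = {
    "diversity": ("diversity_means.csv", "popgen"),
    "differentiation": ("differentiation_by_locus.csv", "popgen"),
    "variance components": ("variance_components.csv", "quantgen"),
    "qst correlations": ("qst_correlations.csv", "matrices"),
    "qst-fst": ("qstfst_table.csv", "qstfst"),
    "tree": ("tree.nwk", "tree"),
}


def report(run_dir) -> str:
    """Plain-text summary of a completed run; absent stages are marked skipped."""
    run_dir = Path(run_dir)
    if not (run_dir / "manifest.json").exists():
        raise ValueError(f"{run_dir} is not a completed run (no manifest)")
    manifest = json.loads((run_dir / "manifest.json").read_text())
    lines = [f"run {run_dir}  (config {manifest['config_hash']})"]
    log = (run_dir / "log.txt").read_text().strip().splitlines() \
        if (run_dir / "log.txt").exists() else []
    for section, (fname, stage) in _SECTIONS.items():
        if (run_dir / fname).exists():
            lines.append(f"  [ok]      {section}: {fname}")
        else:
            lines.append(f"  [skipped] {section} (stage {stage!r} not run)")
    lines += ["", "headline log:"] + [f"  {ln}" for ln in log]
    return "\n".join(lines)
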