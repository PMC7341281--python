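"""End-to-end two-step study: projection validation, then genetic analysis.

Given one configuration (simulated studbook or files on disk), runs:

1. simulate (optional) and write studbook + pedigree,
2. edit to the training dataset (complete 6-season careers) and validate
   both projection methods out-of-sample (PSB/MAD/SDR at k = 3, 4, 5),
3. edit to the full dataset (>= 3 seasons), project incomplete careers and
   assemble the four LFR trait expressions,
4. pedigree kinship (F, A, A^{-1}),
5. REML + BLUP per trait, EBV standardization to the base-year cohort,
6. rank correlations between trait expressions (recorded mares and proven
   stallions) and annual genetic trends.

All randomness flows from the single config seed; rerunning a config
reproduces every output bit-identically.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import kinship as kin
from . import projection as proj
from . import report as rep
from . import reml as remlmod
from . import studbook as sb
from . import synthetic as syn

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    outdir: str = "marelife_out"
    studbook_path: str | None = None
    pedigree_path: str | None = None
    simulation: syn.SimulationConfig | None = None
    rules: sb.EditingRules = field(default_factory=sb.EditingRules)
    traits: tuple = proj.TRAITS
    base_year: int = 2000
    min_daughters: int = 9
    mare_cohort_threshold: int = 100
    sire_cohort_threshold: int = 15
    trend_window: int = 15
    reml_tol: float = 1e-7
    reml_max_iter: int = 100
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        simc = raw.pop("simulation", None)
        rules = raw.pop("rules", None)
        cfg = cls(**raw)
        if simc is not None:
            if "career_length_distribution" in simc:
                simc["career_length_distribution"] = {
                    int(k): float(v)
                    for k, v in simc["career_length_distribution"].items()
                }
            if "birth_year_range" in simc:
                simc["birth_year_range"] = tuple(simc["birth_year_range"])
            cfg.simulation = syn.SimulationConfig(**simc)
        if rules is not None:
            cfg.rules = sb.EditingRules(**rules)
        return cfg

    def validate(self) -> None:
        has_files = self.studbook_path is not None and self.pedigree_path is not None
        if has_files == (self.simulation is not None):
            raise ValueError("exactly one of file paths or a simulation block required")


def _edit(events, pedigree, rules: sb.EditingRules, min_seasons: int):
    import dataclasses

    r = dataclasses.replace(rules, min_seasons=min_seasons)
    return sb.apply_editing(events, pedigree, r)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full study; returns the manifest (also written to outdir)."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "outputs": []}

    def record(stage, **info):
        manifest["stages"][stage] = info

    def save(df: pd.DataFrame, name: str):
        path = out / name
        df.to_csv(path, index=False)
        manifest["outputs"].append(name)

    if config.simulation is not None:
        simc = config.simulation
        pedigree, truth = syn.simulate_pedigree(simc)
        events = syn.simulate_careers(pedigree, truth, simc)
        syn.write_pedigree(pedigree, out / "pedigree.csv")
        syn.write_studbook(events, out / "studbook.csv")
        manifest["outputs"] += ["pedigree.csv", "studbook.csv"]
        events = sb.read_studbook(out / "studbook.csv")
        pedigree = sb.read_pedigree(out / "pedigree.csv")
    else:
        events = sb.read_studbook(config.studbook_path)
        pedigree = sb.read_pedigree(config.pedigree_path)
    record("load", animals=len(pedigree), events=len(events),
           mares=int(events["mare_id"].nunique()))

    training, train_report = _edit(events, pedigree, config.rules, min_seasons=6)
    record("edit_training", **train_report)
    full, full_report = _edit(events, pedigree, config.rules, min_seasons=3)
    record("edit_full", **full_report)
    eu_by = sb.build_eu_by(full)
    record("eu_by", levels=len(eu_by),
           mean_records=float(np.mean(list(eu_by.values()))) if eu_by else 0.0)

    rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(100,)))
    val = proj.validate_projection(training, rng)
    save(val, "projection_validation.csv")
    record("projection_validation", n_training=len(training))

    fits = {
        (m, k): proj.fit_projection(training, m, k)
        for m in ("coefficients", "equations")
        for k in (3, 4, 5)
    }
    km = kin.compute_kinship(pedigree)
    F = pd.Series(km.F, index=km.ids)
    phenos = proj.assemble_phenotypes(full, fits, inbreeding=F)
    save(phenos, "phenotypes.csv")
    record("phenotypes", mares=len(phenos),
           actual=int((phenos["source"] == "actual").sum()),
           projected=int((phenos["source"] == "projected").sum()))

    D_m = km.subset_D(phenos["mare_id"].to_numpy())
    daughters = rep.count_recorded_daughters(pedigree, phenos["mare_id"])
    birth_year = pd.Series(
        pedigree["birth_year"].to_numpy(), index=pedigree["animal_id"].to_numpy()
    )
    sex = pd.Series(pedigree["sex"].to_numpy(), index=pedigree["animal_id"].to_numpy())
    recorded = pd.Series(False, index=birth_year.index)
    recorded.loc[phenos["mare_id"].to_numpy()] = True

    # base-year cohort for standardization; fall back to the nearest birth
    # year that actually has recorded mares (small simulated populations can
    # have empty cohorts in any given calendar year)
    rec_years = np.sort(phenos["birth_year"].unique())
    base_year = config.base_year
    if base_year not in rec_years:
        base_year = int(rec_years[np.argmin(np.abs(rec_years - base_year))])
        record("base_year", requested=config.base_year, used=base_year)

    std_ebvs: dict[str, pd.Series] = {}
    vc_rows = []
    for trait in config.traits:
        vc = remlmod.reml_estimate(
            phenos, km, trait=trait, D_m=D_m,
            tol=config.reml_tol, max_iter=config.reml_max_iter,
        )
        sol = remlmod.solve_blup(phenos, km, vc, trait=trait, D_m=D_m)
        ebv = sol["ebv"]
        std = rep.standardize_ebv(
            ebv, birth_year, recorded, base_year,
            genetic_sd=float(np.sqrt(vc.var_additive)),
        )
        std_ebvs[trait] = std
        vc_rows.append(
            {
                "trait": trait,
                "var_herd": vc.var_herd,
                "var_additive": vc.var_additive,
                "var_dominance": vc.var_dominance,
                "var_residual": vc.var_residual,
                "var_phenotypic": vc.var_phenotypic,
                "h2": vc.h2,
                "se_h2": vc.se_h2,
                "dominance_ratio": vc.dominance_ratio,
                "logL": vc.logL,
                "aic": vc.aic,
                "converged": vc.converged,
                "n_iterations": vc.n_iterations,
            }
        )
        tab = pd.DataFrame(
            {
                "animal_id": ebv.index,
                "ebv": ebv.to_numpy(),
                "std_ebv": std.to_numpy(),
                "birth_year": birth_year.reindex(ebv.index).to_numpy(),
                "sex": sex.reindex(ebv.index).to_numpy(),
                "recorded": recorded.reindex(ebv.index, fill_value=False).to_numpy(),
                "n_recorded_daughters": daughters.reindex(ebv.index, fill_value=0).to_numpy(),
            }
        )
        tab["accuracy"] = [
            rep.accuracy_from_progeny(int(nd), vc.h2)
            for nd in tab["n_recorded_daughters"]
        ]
        save(tab, f"ebv_{trait}.csv")
    vcs = pd.DataFrame(vc_rows)
    save(vcs, "variance_components.csv")
    record("reml", traits=list(config.traits),
           h2={r["trait"]: round(r["h2"], 4) for r in vc_rows})

    mare_ids = phenos["mare_id"].to_numpy()
    stallions = pedigree.loc[
        pedigree["animal_id"].isin(daughters[daughters >= config.min_daughters].index),
        "animal_id",
    ].to_numpy()
    rows = []
    for a, b in itertools.combinations(config.traits, 2):
        rows.append(
            {
                "trait_a": a,
                "trait_b": b,
                "rho_mares": rep.rank_correlation(
                    std_ebvs[a].loc[mare_ids], std_ebvs[b].loc[mare_ids]
                ),
                "rho_stallions": (
                    rep.rank_correlation(
                        std_ebvs[a].loc[stallions], std_ebvs[b].loc[stallions]
                    )
                    if len(stallions) >= 3
                    else np.nan
                ),
            }
        )
    rank = pd.DataFrame(rows)
    save(rank, "rank_correlations.csv")
    record("rank_correlations", n_mares=len(mare_ids), n_stallions=len(stallions))

    trend_frames = []
    for trait in config.traits:
        std = std_ebvs[trait]
        for group, ids, threshold in (
            ("mares", mare_ids, config.mare_cohort_threshold),
            ("sires", stallions, config.sire_cohort_threshold),
        ):
            try:
                tr = rep.genetic_trend(
                    std.loc[ids], birth_year, group, threshold, config.trend_window
                )
            except ValueError as e:
                record(f"trend_{trait}_{group}", error=str(e)[:200])
                continue
            t = tr.table.copy()
            t.insert(0, "group", group)
            t.insert(0, "trait", trait)
            trend_frames.append(t)
    if trend_frames:
        save(pd.concat(trend_frames, ignore_index=True), "genetic_trends.csv")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
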