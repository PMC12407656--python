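"""End-to-end orchestration: simulate -> infer -> score -> associate -> SEM.

A single YAML-configurable run generates a synthetic family study, infers
transmitted/non-transmitted alleles, builds polygenic scores, fits the
association, parent-of-origin, and mediation models, and writes a report with
descriptives (pairs vs trios), effect tables, and mediation path values.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import assoc, io, pathmodels, scores, transmission
from .simfam import PhenoModelParams, simulate_dataset

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all", "descriptives", "fmt_percent"]


@dataclass
class SimulationBlock:
    n_families: int = 300
    n_chromosomes: int = 2
    markers_per_chromosome: int = 500
    length_cm: float = 100.0
    pair_fraction: float = 0.83
    father_masked_share: float = 0.7
    switch_error_rate: float = 0.0
    params: dict = field(default_factory=dict)


@dataclass
class InferenceBlock:
    tile_size: int = 150
    refine: bool = True


@dataclass
class ScoringBlock:
    n_pcs: int = 10
    imputation: str = "role"


@dataclass
class AnalysisBlock:
    outcomes: tuple = tuple(assoc.TABLE2_OUTCOMES)
    bootstrap_b: int = 1000
    fdr_m: int = 5


@dataclass
class RunConfig:
    seed: int
    simulation: SimulationBlock = field(default_factory=SimulationBlock)
    inference: InferenceBlock = field(default_factory=InferenceBlock)
    scoring: ScoringBlock = field(default_factory=ScoringBlock)
    analysis: AnalysisBlock = field(default_factory=AnalysisBlock)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw:
            raise ValueError("config must set a seed")
        return cls(
            seed=int(raw["seed"]),
            simulation=SimulationBlock(**raw.get("simulation", {})),
            inference=InferenceBlock(**raw.get("inference", {})),
            scoring=ScoringBlock(**raw.get("scoring", {})),
            analysis=AnalysisBlock(**raw.get("analysis", {})),
        )


def fmt_percent(count: int, total: int) -> float:
    """Percentage at one decimal, as printed in descriptive tables."""
    return round(100.0 * count / total, 1)


def descriptives(pheno: pd.DataFrame, pedigree: pd.DataFrame) -> pd.DataFrame:
    """Pairs-vs-trios descriptive table.

    Binary variables report n (%) and a chi-square test; continuous variables
    mean +/- SD and a two-sample t-test.  Families are 'trio' when both
    parents are genotyped, 'pair' otherwise.
    """
    parents = pedigree[pedigree["role"].isin(["mother", "father"])]
    n_geno = parents.groupby("family_id")["genotyped"].sum()
    fam_type = n_geno.map(lambda k: "trio" if k == 2 else "pair")
    d = pheno.copy()
    d["fam_type"] = d["family_id"].map(fam_type)

    variables = [
        ("age", "continuous"),
        ("sex", "binary"),
        ("smk_init", "binary"),
        ("cig_day", "continuous"),
        ("pack_years", "continuous"),
        ("alc_gday", "continuous"),
        ("cannabis_ever", "binary"),
    ]
    rows = []
    for var, kind in variables:
        if var not in d:
            continue
        obs = d.dropna(subset=[var])
        grp = {g: obs.loc[obs["fam_type"] == g, var] for g in ("pair", "trio")}
        row = {"variable": var, "type": kind, "n": len(obs)}
        if kind == "binary":
            k = int(obs[var].sum())
            row["summary"] = f"{k} ({fmt_percent(k, len(obs))})"
            tab = [
                [int(grp[g].sum()), int(len(grp[g]) - grp[g].sum())]
                for g in ("pair", "trio")
            ]
            if min(len(grp["pair"]), len(grp["trio"])) > 0 and np.min(tab) >= 0:
                chi2, p, *_ = stats.chi2_contingency(tab, correction=False)
                row["p"] = float(p)
            else:
                row["p"] = np.nan
        else:
            row["summary"] = f"{obs[var].mean():.2f} +/- {obs[var].std():.2f}"
            if min(len(grp["pair"]), len(grp["trio"])) > 1:
                t, p = stats.ttest_ind(grp["pair"], grp["trio"])
                row["p"] = float(p)
            else:
                row["p"] = np.nan
        for g in ("pair", "trio"):
            row[f"n_{g}"] = len(grp[g])
        rows.append(row)
    return pd.DataFrame(rows)


def _build_analysis_frame(dataset, cfg: RunConfig):
    """Infer transmission, score haplotypes, and merge with phenotypes."""
    tmap = transmission.infer_all(
        dataset.haps, dataset.pedigree,
        tile_size=cfg.inference.tile_size, refine=cfg.inference.refine,
    )
    comp = scores.compute_components(tmap, dataset.weights, mean_dosage=dataset.freqs)
    comp = scores.impute_missing_nt(comp, strategy=cfg.scoring.imputation)
    raw = scores.compute_components(tmap, dataset.weights, mean_dosage=dataset.freqs)
    comp[["mnt_raw", "pnt_raw"]] = raw[["mnt", "pnt"]]
    comp = comp.set_index("individual_id")
    std_cols = ["pgs_t", "pgs_nt", "mt", "pt", "mnt_raw", "pnt_raw"]
    comp = scores.residualize_standardize(
        comp, std_cols, pcs=dataset.pcs, batches=dataset.batches,
        n_pcs=cfg.scoring.n_pcs,
    )
    comp = comp.rename(
        columns={"mnt_raw_std": "mnt_std", "pnt_raw_std": "pnt_std"}
    )
    frame = dataset.phenotypes.set_index("individual_id").join(comp, how="inner")
    return tmap, comp, frame.reset_index()


def run_all(config: RunConfig, out_dir) -> dict:
    """Execute every stage and persist intermediates plus a JSON report.

    Idempotent for a fixed config: the same seed reproduces a byte-identical
    report.  A stage failure aborts with the stage name; files written by
    earlier stages are retained.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = {"config": {
        "seed": config.seed,
        "simulation": asdict(config.simulation),
        "inference": asdict(config.inference),
        "scoring": asdict(config.scoring),
        "analysis": {**asdict(config.analysis),
                     "outcomes": list(config.analysis.outcomes)},
    }, "stages": {}}
    timings = {}

    def stage(name):
        t0 = time.time()

        def done(**info):
            report["stages"][name] = dict(info)
            timings[name] = round(time.time() - t0, 2)

        return done

    try:
        mark = stage("simulate")
        sim = config.simulation
        dataset = simulate_dataset(
            n_families=sim.n_families,
            n_chromosomes=sim.n_chromosomes,
            markers_per_chromosome=sim.markers_per_chromosome,
            length_cm=sim.length_cm,
            params=PhenoModelParams(**sim.params),
            pair_fraction=sim.pair_fraction,
            father_masked_share=sim.father_masked_share,
            switch_error_rate=sim.switch_error_rate,
            seed=config.seed,
        )
        io.write_phased_vcf(
            out / "phased.vcf", dataset.gmap,
            {i: dataset.haps.haps[i]
             for i in dataset.pedigree.loc[dataset.pedigree["genotyped"],
                                           "individual_id"]},
        )
        io.write_map_tsv(out / "map.tsv", dataset.gmap)
        io.write_table(out / "pedigree.tsv", dataset.pedigree)
        io.write_table(out / "phenotypes.tsv", dataset.phenotypes)
        io.write_table(out / "weights.tsv", dataset.weights)
        n_trio = int(
            (dataset.pedigree[dataset.pedigree["role"] != "offspring"]
             .groupby("family_id")["genotyped"].sum() == 2).sum()
        )
        mark(n_families=sim.n_families, n_trios=n_trio,
             n_pairs=sim.n_families - n_trio)

        mark = stage("infer_and_score")
        tmap, comp, frame = _build_analysis_frame(dataset, config)
        io.write_table(out / "scores.tsv", comp.reset_index())
        mark(n_offspring_scored=len(comp),
             n_imputed_nt=int(comp["imputed_nt"].sum()))

        mark = stage("descriptives")
        table1 = descriptives(dataset.phenotypes, dataset.pedigree)
        io.write_table(out / "table1.tsv", table1)
        mark(n=len(dataset.phenotypes))

        mark = stage("assoc")
        outcomes = {k: v for k, v in assoc.TABLE2_OUTCOMES.items()
                    if k in config.analysis.outcomes}
        table2 = assoc.run_table2(frame, outcomes=outcomes,
                                  fdr_m=config.analysis.fdr_m)
        io.write_table(out / "table2.tsv", table2)
        mark(n_outcomes=len(table2))

        mark = stage("parent_of_origin")
        table3 = {}
        for outcome in ("cig_day", "pack_years"):
            fit = pathmodels.fit_parent_of_origin(frame, outcome)
            std = fit.standardized_solution()
            wald_t = pathmodels.wald_equality(
                fit, f"{outcome}~mt_std", f"{outcome}~pt_std")
            wald_nt = pathmodels.wald_equality(
                fit, f"{outcome}~mnt_std", f"{outcome}~pnt_std")
            table3[outcome] = {
                "n": fit.n_used,
                "standardized": {k: round(v, 6) for k, v in std.items()},
                "wald_T": {"chi2": round(wald_t.chi2, 4), "p": round(wald_t.p, 4)},
                "wald_NT": {"chi2": round(wald_nt.chi2, 4), "p": round(wald_nt.p, 4)},
            }
        (out / "table3.json").write_text(json.dumps(table3, indent=2, sort_keys=True))
        mark(outcomes=list(table3))

        mark = stage("mediation")
        fig1 = {}
        for label, mediator, outcome in (
            ("maternal_cig_day", "mother_cig_day", "cig_day"),
            ("maternal_pack_years", "mother_pack_years", "pack_years"),
            ("paternal_pack_years", "father_pack_years", "pack_years"),
        ):
            med = pathmodels.fit_mediation(frame, mediator, outcome)
            entry = {k: round(v, 6) if np.isfinite(v) else None
                     for k, v in med.as_dict().items()}
            entry["n"] = med.fit.n_used
            b = config.analysis.bootstrap_b
            if b >= 2:
                def _fitter(d, m=mediator, o=outcome):
                    r = pathmodels.fit_mediation(d, m, o)
                    return {"indirect_T": r.indirect_t, "indirect_NT": r.indirect_nt}

                boot = pathmodels.bootstrap_cis(
                    _fitter, frame, b=b, seed=config.seed)
                entry["bootstrap"] = {
                    "B": b, "failed": boot.b_failed,
                    "ci": {k: [round(x, 6) for x in v] for k, v in boot.ci.items()},
                }
            fi = pathmodels.fit_indices(med.fit)
            entry["fit"] = {"chi2": round(fi.chi2, 4), "df": fi.df,
                            "rmsea": round(fi.rmsea, 4), "cfi": round(fi.cfi, 4)}
            fig1[label] = entry
        (out / "fig1.json").write_text(json.dumps(fig1, indent=2, sort_keys=True))
        mark(models=list(fig1))
    except Exception as exc:
        failed_stage = [s for s in ("simulate", "infer_and_score", "descriptives",
                                    "assoc", "parent_of_origin", "mediation")
                        if s not in report["stages"]]
        raise RuntimeError(
            f"pipeline failed in stage {failed_stage[0] if failed_stage else '?'}: {exc}"
        ) from exc

    report["table1"] = table1.to_dict(orient="records")
    report["table2"] = json.loads(table2.to_json(orient="records"))
    report["table3"] = table3
    report["fig1"] = fig1
    # wall times live in a separate log so the report itself is byte-identical
    # across reruns of the same seed
    (out / "run_log.json").write_text(
        json.dumps({"seed": config.seed, "seconds": timings}, indent=2, sort_keys=True)
    )
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
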