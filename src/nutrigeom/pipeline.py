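"""End-to-end orchestration of the no-choice and choice analyses."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import choice as choice_mod
from . import simulate as sim
from .morphometrics import body_size_pc1
from .surface import (NutrientResponseSurface, by_fdr_stepup, confidence_region,
                      global_maximum, tps_landscape)
from .survival import CoxModel, aic_confidence_set, episode_split
from .yields import summarize_by_diet, yield_table

log = logging.getLogger("nutrigeom")


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (frozenset, set)):
        return sorted(o)
    if isinstance(o, pd.Series):
        return o.to_dict()
    return str(o)


def _config_hash(cfg: sim.SimConfig) -> str:
    payload = json.dumps(asdict(cfg), default=_json_default, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _fit_trait(adults: pd.DataFrame, trait: str, n_sim: int, seed: int) -> dict:
    X = adults[["protein_mg", "carb_mg"]].to_numpy(float)
    y = adults[trait].to_numpy(float)
    fit = NutrientResponseSurface(trait_name=trait).fit(X, y)
    opt = global_maximum(fit, X)
    cr = confidence_region(fit, X, n_sim=n_sim, seed=seed)
    return {
        "fit": fit.summary_dict(),
        "covariance": fit.cov_.tolist(),
        "optimum": {"protein_mg": opt.p_star, "carb_mg": opt.c_star,
                    "value": opt.value, "ratio": opt.ratio,
                    "ratio_label": opt.ratio_label, "boundary": opt.boundary},
        "confidence_region_polygon": cr.polygon.tolist(),
        "n_sim": cr.n_sim,
        "f_pvalue": fit.f_pvalue_,
    }


def run_no_choice_pipeline(
    cfg: sim.SimConfig, out_dir: str | Path, by_sex: bool = True,
    n_sim: int = 500, make_figures: bool = True,
) -> dict:
    """Simulated-cohort pipeline: intake accounting -> PCA -> surfaces
    (+ optima, confidence regions, landscapes) -> Cox model selection ->
    yield table.  Writes JSON/CSV artifacts into ``out_dir`` and returns the
    report dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = sim.simulate_no_choice(cfg)
    log.info("simulated %d subjects (%d slots)", len(records),
             21 * cfg.n_per_diet)

    adults = sim.records_to_adults(records)
    scores, pca = body_size_pc1(adults)
    adults = adults.assign(size_pc1=scores)
    complete = adults.dropna(subset=["size_pc1", "mass_mg"])
    log.info("adults: %d enrolled -> %d with complete traits", len(adults), len(complete))

    groups = {"pooled": complete}
    if by_sex:
        groups["female"] = complete[complete["sex"] == "F"]
        groups["male"] = complete[complete["sex"] == "M"]

    surfaces: dict[str, dict] = {}
    for gname, sub in groups.items():
        for trait in ("mass_mg", "size_pc1", "dev_days"):
            if len(sub) <= 6:
                continue
            key = f"{trait}|{gname}"
            surfaces[key] = _fit_trait(sub, trait, n_sim=n_sim, seed=cfg.seed + 17)
            if trait == "dev_days":
                surfaces[key]["note"] = ("maximum is an undesirable optimum: "
                                         "slowest development")
    fps = [s["f_pvalue"] for s in surfaces.values()]
    rejected = by_fdr_stepup(fps)
    for key, rej in zip(surfaces, rejected):
        surfaces[key]["significant_fdr_by"] = bool(rej)

    if make_figures:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        for trait in ("mass_mg", "size_pc1", "dev_days"):
            sub = groups["pooled"]
            land = tps_landscape(sub[["protein_mg", "carb_mg"]].to_numpy(float),
                                 sub[trait].to_numpy(float))
            fig, ax = plt.subplots(figsize=(5, 4))
            pcm = ax.pcolormesh(land.grid_p, land.grid_c, land.surface, shading="auto")
            fig.colorbar(pcm, ax=ax, label=trait)
            ax.set_xlabel("cumulative protein (mg)")
            ax.set_ylabel("cumulative carbohydrate (mg)")
            fig.savefig(out / f"landscape_{trait}.png", dpi=120)
            plt.close(fig)

    # survival + development Cox model selection
    subjects = sim.records_to_subjects(records)
    dev = subjects.assign(event=(subjects["fate"] == "adult").astype(int))
    srv = subjects.assign(event=(subjects["fate"] == "died").astype(int))
    dev_cands = [
        CoxModel(terms=("pc",), name="pc"),
        CoxModel(terms=("cellulose",), name="cellulose"),
        CoxModel(terms=("pc", "cellulose"), name="pc+cellulose"),
        CoxModel(terms=("pc", "cellulose", "pc:cellulose"), name="pc*cellulose"),
    ]
    for m in dev_cands:
        m.fit(dev)
    dev_cs = aic_confidence_set(dev_cands)

    episodes = episode_split(srv.drop(columns=["fate"]))
    srv_cands = [
        CoxModel(terms=("pc",), name="pc"),
        CoxModel(terms=("cellulose_by_interval",), name="cellulose(t)"),
        CoxModel(terms=("pc", "cellulose_by_interval"), name="pc+cellulose(t)"),
        CoxModel(terms=("pc", "cellulose"), name="pc+cellulose"),
    ]
    for m in srv_cands:
        m.fit(episodes if "cellulose_by_interval" in m.terms else srv)
    srv_cs = aic_confidence_set(srv_cands)

    summaries = summarize_by_diet(records)
    ytab = yield_table(summaries)

    report = {
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "n_enrolled": len(records),
        "pca": {"eigenvalues": pca.eigenvalues_.tolist(),
                "proportion_variance": pca.proportion_variance_.tolist(),
                "pc1_loadings": pca.loadings_[:, 0].tolist()},
        "surfaces": surfaces,
        "development_model_selection": dev_cs.table.to_dict(orient="records"),
        "development_best": dev_cs.best,
        "survival_model_selection": srv_cs.table.to_dict(orient="records"),
        "survival_best": srv_cs.best,
        "yield_table": ytab.to_dict(orient="records"),
    }
    (out / "no_choice_report.json").write_text(
        json.dumps(report, indent=2, default=_json_default, sort_keys=True))
    ytab.to_csv(out / "yield_table.csv", index=False)
    adults.to_csv(out / "adults.csv", index=False)
    (out / "config.json").write_text(
        json.dumps(asdict(cfg), indent=2, default=_json_default, sort_keys=True))
    return report


def run_choice_pipeline(cfg: sim.SimConfig, out_dir: str | Path,
                        backend: str = "glm") -> dict:
    """Choice pipeline: intake targets per group + consumption model selection."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    choice = sim.simulate_choice(cfg)
    if len(choice) == 0:
        raise ValueError("empty choice dataset")
    targets = choice_mod.intake_target_report(choice)
    model = choice_mod.consumption_model(choice, backend=backend)
    protein = choice.groupby("cricket_id").agg(
        sex=("sex", "first"), p=("protein_dish_mg", "sum"))
    report = {
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "intake_targets": [asdict(t) for t in targets],
        "male_vs_female_protein_pct": choice_mod.percent_more(
            protein.loc[protein.sex == "M", "p"].mean(),
            protein.loc[protein.sex == "F", "p"].mean()),
        "consumption_model": {
            "selected": model.selected,
            "selected_terms": list(model.selected_terms),
            "coef": model.coef.to_dict(),
            "sigma": model.sigma,
            "shape": model.shape,
            "zero_replacement": model.zero_replacement,
            "table": model.table.to_dict(orient="records"),
        },
    }
    (out / "choice_report.json").write_text(
        json.dumps(report, indent=2, default=_json_default, sort_keys=True))
    (out / "config.json").write_text(
        json.dumps(asdict(cfg), indent=2, default=_json_default, sort_keys=True))
    return report
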