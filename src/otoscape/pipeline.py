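"""End-to-end workflow: baseline → ensemble → isoscapes → assignment.

``run_pipeline`` executes the whole synthetic-or-real workflow from one
config: prepare and balance the baseline, fit the ensemble and classify
adults, build per-year per-contingent isoscapes, compute posterior /
binary / summary surfaces, and validate the isoscape against known-origin
fish. Outputs (CSV, JSON, netCDF) plus a run manifest land in one
directory; identical config and seeds reproduce identical CSV/JSON.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd

from . import assignment as asg
from . import baseline as bl
from . import ensemble as ens
from . import isoscape as iso
from . import synthetic as syn
from .config import RunManifest, load_config


def run_pipeline(config_path=None, out_dir="pipeline_out") -> RunManifest:
    """Run the full synthetic workflow; returns the populated manifest."""
    cfg = load_config(config_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=cfg)

    scfg = syn.SyntheticConfig(
        seed=cfg["synthetic"]["seed"],
        year_classes=tuple(cfg["synthetic"]["year_classes"]),
        n_per_cell=cfg["synthetic"]["n_per_cell"],
        sigma_analytical=cfg["assignment"]["sigma_analytical"],
        sigma_within_pop=cfg["assignment"]["sigma_within_pop"],
    )

    # -- step A: baseline ---------------------------------------------------
    with manifest.timed("baseline"):
        raw = syn.gen_baseline(scfg)
        adults_raw = syn.gen_adults(
            scfg, n_per_year_class=cfg["synthetic"]["n_adults_per_year_class"])
        eligible = bl.filter_baseline(
            raw, cfg["baseline"]["max_baseline_age"])
        balanced = bl.oversample_balance(
            eligible, seed=cfg["baseline"]["seed"],
            equalize_year_classes=cfg["baseline"]["equalize_year_classes"])
        ds = bl.standardize(balanced)
        bl.write_otolith_csv(raw, out / "baseline.csv")
        bl.write_otolith_csv(adults_raw, out / "adults.csv")

    # -- step B: ensemble classification ------------------------------------
    with manifest.timed("ensemble"):
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            model, reports = ens.fit_ensemble(
                ds,
                names=cfg["ensemble"]["classifiers"],
                folds=cfg["ensemble"]["folds"],
                seed=cfg["ensemble"]["seed"],
                accuracy_cutoff=cfg["ensemble"]["accuracy_cutoff"],
                top_k=cfg["ensemble"]["top_k"],
                threshold=cfg["ensemble"]["threshold"],
                grids=cfg["ensemble"]["grids"],
            )
        for w in caught:
            manifest.warn("ensemble", str(w.message))
        ens.save_model(model, out / "model")
        usable, excluded = bl.prepare_adults(
            adults_raw, ds, strict=cfg["baseline"]["strict_year_class"])
        if len(excluded):
            manifest.warn("ensemble",
                          f"{len(excluded)} adults outside baseline "
                          "year-classes excluded")
        assignments = model.assign(usable)
        assignments.to_csv(out / "assignments.csv", index=False)
        composition = ens.composition_report(assignments)
        composition.to_csv(out / "composition.csv", index=False)

    # -- step C: isoscapes ---------------------------------------------------
    with manifest.timed("isoscape"):
        masks = syn.gen_masks(scfg)
        lines = syn.default_mixing_lines(scfg, masks)
        frac = iso.FractionationModel(
            gamma=cfg["isoscape"]["gamma"], beta=cfg["isoscape"]["beta"])
        isoscapes: dict[tuple[str, int], iso.Isoscape] = {}
        for year in scfg.year_classes:
            T, S = syn.gen_ocean(scfg, year, masks)
            for cont in ("northern", "southern"):
                scape = iso.build_isoscape(
                    T, S, year, cont, lines, frac,
                    domain_mask=masks[cont], shelf_mask=masks["shelf"],
                    strict=cfg["isoscape"]["strict_months"])
                isoscapes[(cont, year)] = scape
                iso.write_isoscape(
                    scape, out / f"iso_{year}_{cont}.nc")

    # -- steps D–F: continuous assignment ------------------------------------
    with manifest.timed("assignment"):
        vm = asg.VarianceModel(cfg["assignment"]["sigma_analytical"],
                               cfg["assignment"]["sigma_within_pop"])
        q = cfg["assignment"]["quantile"]
        merged = assignments.merge(
            adults_raw[["fish_id", "d18o"]], on="fish_id")
        surfaces, binaries, summaries = asg.assign_fish(
            merged, isoscapes, vm, q=q)
        index_rows = []
        for sm in summaries:
            fn = f"summary_{sm.year_class}_{sm.contingent}.nc"
            sm.values.to_dataset(name="fraction_assigned").to_netcdf(
                out / fn, engine="scipy")
            index_rows.append({"year_class": sm.year_class,
                               "contingent": sm.contingent,
                               "n_fish": sm.n_fish, "file": fn})
        pd.DataFrame(index_rows).to_csv(out / "summary_index.csv",
                                        index=False)

    # -- step G: validation ---------------------------------------------------
    with manifest.timed("validation"):
        sub_masks = {k: masks[k] for k in syn.SUBREGION_NAMES}
        vyear = scfg.year_classes[0]
        viso = isoscapes[("southern", vyear)]
        fish = syn.gen_known_origin_fish(
            scfg, viso, cfg["synthetic"]["n_validation_fish"], sub_masks)
        fish.to_csv(out / "age0.csv", index=False)
        val_isoscapes = {vyear: viso}
        curve = asg.threshold_sweep(
            fish, val_isoscapes, vm, sub_masks,
            floor=cfg["assignment"]["sweep_floor"])
        curve.to_frame().to_csv(out / "validation_curve.csv", index=False)
        if curve.chosen is None:
            manifest.warn("validation",
                          "no sweep threshold met the accuracy floor")
        acc_at_q = asg.validate(fish, val_isoscapes, vm, sub_masks, q=q)
        manifest.config["results"] = {
            "ensemble_cv_accuracy": reports[-1].mean_accuracy,
            "ensemble_cv_auc": reports[-1].mean_auc,
            "ensemble_cv_logloss": reports[-1].mean_logloss,
            "pct_unassigned_adults": float(
                100.0 * (assignments["decision"] == "unassigned").mean()),
            "validation_accuracy_at_q": acc_at_q,
            "chosen_threshold": curve.chosen,
        }

    for f in sorted(out.glob("*.csv")) + sorted(out.glob("*.nc")):
        manifest.add_output(f)
    if config_path is not None:
        manifest.add_input(config_path)
    manifest.write(out / "manifest.json")
    return manifest
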