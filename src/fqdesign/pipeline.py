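"""End-to-end workflow: prepare, align, fields, fit, validate, design, screen.

``run_pipeline`` executes the stages in order on the bundled (or
user-supplied) structure set and activity table, writing each stage's outputs
under an output directory together with the fully serialized configuration,
so a rerun with the same config and seed is byte-identical on the numeric
outputs. A failing stage is recorded and its dependents are skipped; the
report bundle carries per-stage status.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import chem, contours, endpoints, fields, pls, synth, validation

logger = logging.getLogger("fqdesign")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


class PipelineConfig(BaseModel):
    """Validated settings for the full workflow."""

    # inputs; None -> bundled fixtures
    structures: str | None = None        # SMILES<TAB>id file
    activity_table: str | None = None    # id,set,experimental columns
    template_id: str = "Trovafloxacin"
    parent_id: str = "Trovafloxacin"
    out_dir: str = "fqdesign_out"
    seed: int = 2020

    # preparation / alignment
    n_embed_attempts: int = Field(10, ge=1)
    core_smarts: str = chem.QUINOLONE_CORE_SMARTS
    max_core_rmsd: float = Field(1.0, gt=0)

    # grid / probe / filtering
    spacing: float = Field(2.0, gt=0)
    margin: float = Field(4.0, ge=0)
    alpha: float = Field(0.3, gt=0)
    filter_sd: float = Field(0.05, ge=0)

    # PLS / contours
    max_components: int = Field(8, ge=1)
    fav_pct: float = 80.0
    disfav_pct: float = 20.0
    site_radius: float = Field(3.0, ge=0)

    @model_validator(mode="after")
    def _percentiles_ordered(self):
        if self.fav_pct <= self.disfav_pct:
            raise ValueError("fav_pct must exceed disfav_pct")
        return self


@dataclass
class PipelineResult:
    config: PipelineConfig
    stages: dict[str, str] = field(default_factory=dict)  # stage -> ok/error/skipped
    model: pls.PLSModel | None = None
    cv: pls.CVResult | None = None
    validation: validation.ValidationReport | None = None
    screened: list[str] | None = None
    outputs: dict[str, str] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return all(v == "ok" for v in self.stages.values())


def _load_inputs(cfg: PipelineConfig):
    if cfg.structures:
        mols = chem.read_smiles_file(cfg.structures)
    else:
        mols = synth.load_fixture("quinolones.smi")
    if cfg.activity_table:
        table = pd.read_csv(cfg.activity_table)
    else:
        table = synth.load_fixture("table1")
    return mols, table


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Run prepare -> align -> fields -> fit/select -> validate -> contours ->
    enumerate -> screen -> post-analysis, writing outputs under ``cfg.out_dir``."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    res = PipelineResult(config=cfg)
    (out / "config.json").write_text(cfg.model_dump_json(indent=2))

    def stage(name, fn, *deps):
        if any(res.stages.get(d) != "ok" for d in deps):
            res.stages[name] = "skipped"
            logger.warning("stage %s skipped (failed dependency)", name)
            return None
        t0 = time.perf_counter()
        try:
            value = fn()
        except Exception as exc:  # noqa: BLE001 - stage errors are reported
            res.stages[name] = f"error: {exc}"
            logger.error("stage %s failed: %s", name, exc)
            return None
        res.stages[name] = "ok"
        logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
        return value

    state: dict = {}

    def _prepare():
        mols, table = _load_inputs(cfg)
        state["table"] = table
        state["prepared"] = [
            chem.prepare_molecule(m, seed=cfg.seed, n_embed_attempts=cfg.n_embed_attempts)
            for m in mols
        ]

    stage("prepare", _prepare)

    def _align():
        prepared = state["prepared"]
        by_id = {m.id: m for m in prepared}
        template = by_id[cfg.template_id]
        spec = chem.AlignmentSpec(
            template_id=cfg.template_id,
            core_smarts=cfg.core_smarts,
            max_core_rmsd=cfg.max_core_rmsd,
        )
        aset = chem.align_set(prepared, template, spec)
        state["aset"] = aset
        chem.write_sdf(aset.members, out / "aligned.sdf")
        res.outputs["aligned"] = str(out / "aligned.sdf")

    stage("align", _align, "prepare")

    def _fields():
        aset = state["aset"]
        grid = fields.build_grid(aset, spacing=cfg.spacing, margin=cfg.margin)
        probe = fields.ProbeSpec(alpha=cfg.alpha)
        desc = fields.compute_descriptor_matrix(
            aset, grid, probe=probe, filter_sd=cfg.filter_sd
        )
        state["desc"] = desc
        ids = desc.molecule_ids
        X = desc.assemble(scaled=True)
        pd.DataFrame(X, index=ids).to_csv(out / "descriptors.csv")
        res.outputs["descriptors"] = str(out / "descriptors.csv")

    stage("fields", _fields, "align")

    def _fit():
        desc, table = state["desc"], state["table"]
        table = table.set_index("id").loc[desc.molecule_ids].reset_index()
        train = table["set"] == "train"
        X = desc.assemble(scaled=True)
        y = table["experimental"].to_numpy(dtype=float)
        Xtr, ytr = X[train.to_numpy()], y[train.to_numpy()]
        max_n = min(cfg.max_components, len(ytr) - 2)
        cv = pls.select_components(Xtr, ytr, max_n)
        model = pls.fit_pls(Xtr, ytr, cv.chosen_n)
        yhat = model.predict(Xtr)
        stats = pls.model_stats(ytr, yhat, cv.chosen_n)
        model.q2 = cv.q2_by_n[cv.chosen_n]
        model.r2, model.see, model.f_stat = stats["r2"], stats["see"], stats["f_stat"]
        model.field_contributions = pls.field_contributions(
            model.coef, desc.column_sds(scaled=True), desc.column_fields()
        )
        model.metadata = {
            "force_field": "MMFF94",
            "charges": "Gasteiger",
            "grid": {"spacing": cfg.spacing, "margin": cfg.margin,
                     "dims": list(desc.grid.dims), "origin": list(desc.grid.origin)},
            "probe": {"alpha": cfg.alpha},
            "filter_sd": cfg.filter_sd,
            "block_scale": desc.block_scale,
            "seed": cfg.seed,
            "train_ids": table.loc[train, "id"].tolist(),
        }
        res.model, res.cv = model, cv
        state.update(model=model, cv=cv, table=table, train_mask=train.to_numpy(), X=X, y=y)
        (out / "model.json").write_text(model.to_json())
        res.outputs["model"] = str(out / "model.json")

    stage("fit", _fit, "fields")

    def _validate():
        table, X = state["table"], state["X"]
        model, train = state["model"], state["train_mask"]
        test = ~train
        preds = model.predict(X[test])
        rep = validation.r2_pred(
            test_exp=state["y"][test],
            test_pred=preds,
            train_exp=state["y"][train],
            ids=table.loc[test, "id"].tolist(),
        )
        res.validation = rep
        rep.to_frame().to_csv(out / "validation.csv", index=False)
        (out / "validation.json").write_text(json.dumps(rep.to_dict(), indent=2))
        res.outputs["validation"] = str(out / "validation.csv")

    stage("validate", _validate, "fit")

    def _contours():
        cmap = contours.stdev_coeff_map(state["model"], state["desc"])
        contours.threshold_contours(cmap, cfg.fav_pct, cfg.disfav_pct)
        cmap.to_frame().to_csv(out / "contours.csv", index=False)
        res.outputs["contours"] = str(out / "contours.csv")

    stage("contours", _contours, "fit")

    def _enumerate():
        specs, errors = contours.enumerate_derivatives(contours.SubstitutionScheme())
        for name, msg in errors:
            logger.warning("derivative %s rejected: %s", name, msg)
        with open(out / "derivatives.smi", "w") as fh:
            from rdkit import Chem as _C

            for s in specs:
                fh.write(f"{_C.MolToSmiles(s.molecule.mol)}\t{s.name}\n")
        res.outputs["derivatives"] = str(out / "derivatives.smi")
        state["derivatives"] = specs

    stage("enumerate", _enumerate)

    def _screen():
        t2 = synth.load_fixture("table2")
        parent_logfb = float(
            state["table"].set_index("id").loc[cfg.parent_id, "experimental"]
        ) if "table" in state else 1.748
        screened = endpoints.screen_lower_binding(
            t2.rename(columns={"logfb_pred": "logfb"}), parent_logfb
        )
        res.screened = screened
        rows = t2[t2["id"].isin(screened)].copy()
        rows["fb_from_logfb"] = [endpoints.log_fb_to_fb(v) for v in rows["logfb_pred"]]
        rows.to_csv(out / "screening.csv", index=False)
        (out / "screening.json").write_text(json.dumps(screened, indent=2))
        res.outputs["screening"] = str(out / "screening.csv")

    stage("screen", _screen, "prepare")

    def _post():
        t5 = synth.load_fixture("table5")
        t5["delta_g_recomputed"] = [
            endpoints.delta_g(r, p)
            for r, p in zip(t5["g_reactants_hartree"], t5["g_products_hartree"])
        ]
        t4 = synth.load_fixture("table4")
        t4["stable"] = [
            endpoints.stability_check(endpoints.FrequencySet(i, [f]))
            for i, f in zip(t4["id"], t4["min_frequency_cm1"])
        ]
        t7 = synth.load_fixture("table7")
        counts = {
            col.removeprefix("n_"): endpoints.classify_contacts(
                list(zip(t7["residue"], t7[col]))
            )
            for col in ("n_trovafloxacin", "n_derivative_10")
        }
        t8 = synth.load_fixture("table8")
        dists = {
            cid: endpoints.mean_contact_distance(g["distance_A"].tolist())
            for cid, g in t8.groupby("compound")
        }
        post = {
            "delta_g_kcal_mol": dict(zip(t5["path"], t5["delta_g_recomputed"])),
            "all_stable": bool(t4["stable"].all()),
            "contact_counts": counts,
            "mean_contact_distance_A": dists,
        }
        (out / "post_analysis.json").write_text(json.dumps(post, indent=2))
        res.outputs["post_analysis"] = str(out / "post_analysis.json")

    stage("post", _post)

    (out / "stages.json").write_text(json.dumps(res.stages, indent=2))
    return res
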