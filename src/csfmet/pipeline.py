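"""End-to-end pipeline orchestration with run configuration and provenance.

A :class:`RunConfig` carries per-stage parameters (every stochastic stage has
an explicit seed) and round-trips losslessly through YAML/JSON.
:func:`run_pipeline` executes
simulate -> preprocess -> univariate -> model -> panel -> sus -> network ->
pathway as configured, writing each stage's outputs plus a provenance record
(config echo, config hash, seeds, package version). Runs are idempotent for
a fixed config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from csfmet import __version__
from csfmet.datatypes import GROUPS, ValidationError, rpair_table
from csfmet.io import read_dataset, write_dataset
from csfmet.latent import OPLS, PLSDA, q2_cv
from csfmet.network import annotate_nodes, build_network, enrich_pathways, export_sif
from csfmet.panel import build_panel, joint_panel, sweep_panel_size, vip_ranking
from csfmet.preprocess import autoscale, impute_missing, occurrence_filter, sum_normalize
from csfmet.simulate import design_from_table1, generate
from csfmet.sus import classify_regions, kmeans_confirm, merged_gradual_screen, sus_coordinates
from csfmet.univariate import contrast_stats

logger = logging.getLogger(__name__)

_STAGES = ("simulate", "preprocess", "univariate", "model", "panel", "sus",
           "network", "pathway")


@dataclass
class RunConfig:
    """Per-stage run parameters; see module docstring."""

    out_dir: str = "csfmet_run"
    seed: int = 0
    input_dir: str | None = None  # read an existing dataset instead of simulating
    simulate: dict = field(default_factory=lambda: {"seed": 0})
    preprocess: dict = field(default_factory=lambda: {
        "min_frac": 0.5, "impute": "half_min", "transform": "log", "scaling": "uv",
    })
    univariate: dict = field(default_factory=lambda: {"alpha": 0.05, "welch": False,
                                                      "adjust": False})
    model: dict = field(default_factory=lambda: {
        "a_pred": 3, "a_orth": 2, "folds": 7, "cv_seed": 0,
    })
    panel: dict = field(default_factory=lambda: {
        "k": 8, "k_min": 2, "k_max": 20, "n_boot": 500, "seed": 0,
        "clinical": ["edss", "ocb", "protein"],
    })
    sus: dict = field(default_factory=lambda: {
        "disease": "ALL", "c_contrib": 0.3, "c_axis": 0.08, "c_diag": 0.08,
        "k": 2, "seed": 0, "restarts": 20,
    })
    network: dict = field(default_factory=lambda: {"cutoff": 0.7, "alpha": 0.05})
    pathway: dict = field(default_factory=lambda: {"adjust": False})

    def validate(self) -> "RunConfig":
        for stage in ("simulate", "panel", "sus"):
            d = getattr(self, stage)
            if "seed" not in d or d["seed"] is None:
                raise ValidationError(f"stage {stage!r} has no explicit seed")
        if "cv_seed" not in self.model or self.model["cv_seed"] is None:
            raise ValidationError("stage 'model' has no explicit cv_seed")
        return self

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        cfg = cls()
        for k, v in d.items():
            if not hasattr(cfg, k):
                raise ValidationError(f"unknown config key {k!r}")
            cur = getattr(cfg, k)
            if isinstance(cur, dict) and isinstance(v, dict):
                cur.update(v)
            else:
                setattr(cfg, k, v)
        return cfg.validate()

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text(encoding="utf-8")
        data = (json.loads(text) if str(path).endswith(".json")
                else yaml.safe_load(text))
        return cls.from_dict(data or {})

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _write_tsv(df: pd.DataFrame, path: Path, cfg_hash: str, index_label=None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, sep="\t", index_label=index_label)


def _write_json(obj: dict, path: Path, cfg_hash: str) -> None:
    obj = {"config_hash": cfg_hash, **obj}
    path.write_text(json.dumps(obj, indent=2, default=_json_default) + "\n",
                    encoding="utf-8")


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serializable: {type(o)}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns a result bundle (also written to disk).

    Any stage failure aborts with the stage name and cause.
    """
    config.validate()
    h = config.hash()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"config_hash": h}
    stage = "setup"
    try:
        stage = "simulate"
        if config.input_dir:
            d = Path(config.input_dir)
            fmt = "tsv" if (d / "matrix.tsv").exists() else "csv"
            ds = read_dataset(d / f"matrix.{fmt}", d / f"samples.{fmt}",
                              d / f"metabolites.{fmt}")
        else:
            design = design_from_table1(seed=config.simulate["seed"])
            ds = generate(design)
            write_dataset(ds, out / "dataset")
        bundle["dataset"] = ds

        stage = "preprocess"
        p = config.preprocess
        norm = sum_normalize(ds.matrix)
        filt = occurrence_filter(norm, ds.samples, p["min_frac"])
        imp = impute_missing(filt, p["impute"])
        X, state = autoscale(imp, transform=p["transform"], mode=p["scaling"])
        _write_tsv(imp.values, out / "normalized.tsv", h, index_label="sample_id")
        _write_tsv(X, out / "scaled.tsv", h, index_label="sample_id")
        bundle.update(normalized=imp, scaled=X, scaling_state=state)

        stage = "univariate"
        u = config.univariate
        contrasts = {}
        tables = []
        specs = [("CTRL", "MS"), ("CTRL", "NMOSD"), ("CTRL", "ITM"),
                 ("CTRL", ("MS", "NMOSD", "ITM"))]
        for ref, case in specs:
            res = contrast_stats(imp, ds.samples, ref, case, alpha=u["alpha"],
                                 welch=u["welch"], adjust=u["adjust"])
            contrasts[res.contrast] = res
            t = res.table.copy()
            t.insert(0, "contrast", res.contrast)
            tables.append(t)
        _write_tsv(pd.concat(tables), out / "univariate.tsv", h,
                   index_label="metabolite")
        bundle["contrasts"] = contrasts

        stage = "model"
        mc = config.model
        groups = ds.samples.loc[X.index, "group"].to_numpy()
        opls = OPLS(X.to_numpy(), groups, feature_names=list(X.columns)).fit(
            mc["a_pred"], mc["a_orth"])
        opls.q2 = q2_cv(X.to_numpy(), groups, mc["a_pred"], mc["a_orth"],
                        folds=mc["folds"], seed=mc["cv_seed"],
                        sample_ids=list(X.index))
        plsda = PLSDA(X.to_numpy(), groups, feature_names=list(X.columns)).fit(
            mc["a_pred"])
        scores = pd.DataFrame(
            opls.scores, index=X.index,
            columns=[f"T{i+1}" for i in range(opls.n_pred)])
        _write_tsv(scores, out / "scores.tsv", h, index_label="sample_id")
        _write_tsv(opls.vip().to_frame(), out / "vip.tsv", h,
                   index_label="metabolite")
        _write_json({"r2y_cum": opls.r2y_cum, "q2_cum": opls.q2,
                     "a_pred": opls.n_pred, "a_orth": opls.n_orth,
                     "plsda_r2y_cum": plsda.r2y_cum},
                    out / "model.json", h)
        bundle.update(opls=opls, plsda=plsda)

        stage = "panel"
        pc = config.panel
        vip_order = list(opls.vip().sort_values(ascending=False).index)
        pm = build_panel(X, groups, vip_order[:pc["k"]],
                         n_boot=pc["n_boot"], seed=pc["seed"])
        sweep = sweep_panel_size(X, groups, vip_order, pc["k_min"], pc["k_max"])
        jm = joint_panel(X, ds.samples, groups, clinical=tuple(pc["clinical"]),
                         k=10, n_boot=pc["n_boot"], seed=pc["seed"])
        _write_tsv(sweep, out / "panel_sweep.tsv", h, index_label="k")
        report = {
            "metabolite_panel": {
                "features": pm.features,
                "aucs": pm.aucs,
                "ci": {g: [rc.ci_low, rc.ci_high] for g, rc in pm.curves.items()},
            },
            "joint_panel": {
                "features": jm.features,
                "aucs": jm.aucs,
                "ci": {g: [rc.ci_low, rc.ci_high] for g, rc in jm.curves.items()},
            },
            "sweep_best_k": sweep.attrs["best_k"],
            "sweep_plateau": sweep.attrs["plateau"],
        }
        _write_json(report, out / "panel.json", h)
        for g, rc in pm.curves.items():
            _write_tsv(pd.DataFrame({"fpr": rc.fpr, "tpr": rc.tpr,
                                     "threshold": rc.thresholds}),
                       out / f"roc_{g}_vs_rest.tsv", h, index_label="i")
        bundle.update(panel=pm, joint=jm, sweep=sweep)

        stage = "sus"
        sc = config.sus
        coords = classify_regions(
            sus_coordinates(X, ds.samples, sc["disease"]),
            c_contrib=sc["c_contrib"], c_axis=sc["c_axis"], c_diag=sc["c_diag"])
        _write_tsv(coords.table, out / "sus.tsv", h, index_label="metabolite")
        merged = merged_gradual_screen(
            X, imp, ds.samples,
            c_contrib=sc["c_contrib"], c_axis=sc["c_axis"], c_diag=sc["c_diag"])
        cluster_report = {}
        if len(merged) >= max(2, sc["k"]):
            assign, creport = kmeans_confirm(X, ds.samples, merged, k=sc["k"],
                                             seed=sc["seed"],
                                             restarts=sc["restarts"])
            cluster_report = {"assignment": assign.to_dict(),
                              "clusters": creport.to_dict(orient="index")}
        _write_json({"merged_gradual": merged, "thresholds": coords.thresholds,
                     "kmeans": cluster_report}, out / "sus.json", h)
        bundle.update(sus=coords, merged_gradual=merged)

        stage = "network"
        nc = config.network
        rpairs = rpair_table(ds.metabolites)
        net = build_network(ds.metabolites, cutoff=nc["cutoff"], rpairs=rpairs)
        key = "CTRL_vs_MS+NMOSD+ITM"
        net = annotate_nodes(net, contrasts[key], alpha=nc["alpha"])
        export_sif(net, out / "network.sif")
        bundle["network"] = net

        stage = "pathway"
        hits = set(merged)
        enr = enrich_pathways(hits, ds.metabolites, rpairs,
                              adjust=config.pathway["adjust"])
        _write_tsv(enr, out / "pathway.tsv", h, index_label="pathway")
        bundle["pathways"] = enr

        _write_json(
            {"version": __version__, "config": config.to_dict(),
             "stages": list(_STAGES)},
            out / "provenance.json", h)
    except Exception as e:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e
    return bundle
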