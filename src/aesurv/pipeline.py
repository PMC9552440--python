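"""Stage orchestration: config validation, caching, reproducibility manifest.

A single YAML config drives the whole pipeline
(simulate → preprocess → train-ae → subtype → classify → evaluate →
drivers).  Each stage reads and writes only files under the configured
output directory, records SHA-256 digests of its outputs in the run
manifest, and is skipped when its outputs already exist (unless forced).
One global seed yields deterministic per-stage sub-seeds, so a run is
bit-reproducible end to end.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import autoencoder as _ae
from . import classify as _classify
from . import drivers as _drivers
from . import io as _io
from . import metrics as _metrics
from . import preprocess as _prep
from . import simulate as _sim
from . import subtype as _subtype
from .exceptions import ConfigurationError

log = logging.getLogger("aesurv")

DEFAULTS: dict = {
    "simulate": None,
    "inputs": None,
    "preprocess": {"mad_min": 0.0, "mad_top_k": None, "scaler_mode": "robust",
                   "squash_epsilon": 0.01},
    "autoencoder": {"hidden_sizes": [500, 100, 500], "l1_weight": 1e-4,
                    "l2_activity": 1e-3, "learning_rate": 1e-3, "epochs": 20,
                    "batch_size": 32, "dropout": 0.5},
    "subtype": {"alpha": 0.05, "k_min": 2, "k_max": 6},
    "classify": {"top_k": 100, "n_splits": 10, "train_fraction": 0.6, "svm": {}},
    "drivers": {"r_threshold": -0.3, "p_threshold": 0.05},
    "enrich": {"gmt": None, "alpha": 0.01},
}
REQUIRED = ("seed", "outdir")
STAGES = ("simulate", "preprocess", "train-ae", "subtype", "classify",
          "evaluate", "drivers")


def load_config(path) -> dict:
    """Load and validate a pipeline config file, merging stage defaults."""
    return validate_config(yaml.safe_load(Path(path).read_text()) or {})


def validate_config(raw: dict) -> dict:
    """Validate a raw config mapping and merge stage defaults."""
    missing = [k for k in REQUIRED if k not in raw]
    if missing:
        raise ConfigurationError(f"config missing required key(s): {missing}")
    unknown = [k for k in raw if k not in set(DEFAULTS) | set(REQUIRED)]
    if unknown:
        raise ConfigurationError(f"unknown config key(s): {unknown}")
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULTS.items()}
    for k, v in raw.items():
        if isinstance(cfg.get(k), dict) and isinstance(v, dict):
            bad = [kk for kk in v if kk not in cfg[k]]
            if bad:
                raise ConfigurationError(f"unknown key(s) in config section {k!r}: {bad}")
            cfg[k].update(v)
        else:
            cfg[k] = v
    if cfg["simulate"] is None and cfg["inputs"] is None:
        raise ConfigurationError("config needs either a 'simulate' or an 'inputs' section")
    cfg["seed"] = int(cfg["seed"])
    return cfg


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed below 2^31."""
    return (seed * 1000003 + STAGES.index(stage)) % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _digest_tree(paths) -> dict[str, str]:
    out = {}
    for p in sorted(Path(x) for x in paths):
        if p.is_dir():
            for f in sorted(p.rglob("*")):
                if f.is_file():
                    out[str(f)] = _sha256(f)
        elif p.is_file():
            out[str(p)] = _sha256(p)
    return out


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, sort_keys=True, indent=1, default=str))


class PipelineRunner:
    """Executes pipeline stages against one config, tracking a manifest."""

    def __init__(self, config: dict | str | Path, force: bool = False):
        self.cfg = (validate_config(config) if isinstance(config, dict)
                    else load_config(config))
        self.out = Path(self.cfg["outdir"])
        self.out.mkdir(parents=True, exist_ok=True)
        self.force = force
        self.manifest = {"config": self.cfg, "seed": self.cfg["seed"], "stages": {}}

    # -- helpers ---------------------------------------------------------

    def _run(self, name: str, outputs: list[Path], fn) -> None:
        if not self.force and outputs and all(Path(o).exists() for o in outputs):
            log.info("stage %s: outputs exist, skipped", name)
            self.manifest["stages"][name] = {
                "skipped": True, "outputs": _digest_tree(outputs)}
            return
        t0 = _time.time()
        fn()
        self.manifest["stages"][name] = {
            "skipped": False,
            "elapsed_s": round(_time.time() - t0, 3),
            "outputs": _digest_tree(outputs),
        }

    def _data_paths(self) -> dict[str, Path]:
        if self.cfg["inputs"]:
            return {k: Path(v) for k, v in self.cfg["inputs"].items()}
        d = self.out / "data"
        return {"expr": d / "expr.tsv", "meth": d / "meth.tsv",
                "clinical": d / "clinical.tsv"}

    # -- stages ----------------------------------------------------------

    def simulate(self) -> None:
        if self.cfg["simulate"] is None:
            return
        params = dict(self.cfg["simulate"])
        params.setdefault("seed", stage_seed(self.cfg["seed"], "simulate"))
        conf = _sim.SyntheticConfig(**params)
        d = self.out / "data"

        def fn():
            _sim.write_cohort(_sim.generate_cohort(conf), d)

        self._run("simulate", [d / "expr.tsv", d / "meth.tsv",
                               d / "clinical.tsv", d / "truth.tsv"], fn)

    def preprocess(self) -> None:
        p = self.cfg["preprocess"]
        d = self.out / "prep"
        outputs = [d / f"{o}_{t}.tsv" for o in ("expr", "meth")
                   for t in ("scaled", "squashed")] + [d / "clinical.tsv"]

        def fn():
            d.mkdir(parents=True, exist_ok=True)
            paths = self._data_paths()
            omics = {"expr": _io.read_omics(paths["expr"]),
                     "meth": _io.read_omics(paths["meth"])}
            clinical = _io.read_clinical(paths["clinical"])
            mats, clinical = _io.align_samples(list(omics.values()), clinical)
            for name, m in zip(omics, mats):
                m = _prep.mad_filter(m, p["mad_min"], p["mad_top_k"])
                scaler = _prep.fit_scaler(m, mode=p["scaler_mode"])
                scaled = _prep.apply_scaler(m, scaler)
                _io.write_omics(scaled, d / f"{name}_scaled.tsv")
                _io.write_omics(
                    _prep.squash_to_unit(scaled, p["squash_epsilon"]),
                    d / f"{name}_squashed.tsv")
            _io.write_clinical(clinical, d / "clinical.tsv")

        self._run("preprocess", outputs, fn)

    def train_ae(self) -> None:
        a = dict(self.cfg["autoencoder"])
        d = self.out
        model_dir = d / "model"
        latent_path = d / "latent.tsv"

        def fn():
            expr = _io.read_omics(d / "prep" / "expr_squashed.tsv")
            meth = _io.read_omics(d / "prep" / "meth_squashed.tsv")
            stacked = pd.concat([expr, meth], axis=0, keys=["expr", "meth"])
            stacked.index = [f"{o}:{f}" for o, f in stacked.index]
            model = _ae.Autoencoder(
                hidden_sizes=tuple(a["hidden_sizes"]),
                l1_weight=a["l1_weight"], l2_activity=a["l2_activity"],
                learning_rate=a["learning_rate"], epochs=a["epochs"],
                batch_size=a["batch_size"], dropout=a["dropout"],
                random_state=stage_seed(self.cfg["seed"], "train-ae"),
            )
            model.fit(stacked.T.to_numpy(dtype=float))
            model.save(model_dir)
            latent = _ae.encode(model, stacked)
            latent.T.to_csv(latent_path, sep="\t",
                            float_format=_io.FLOAT_FORMAT, index_label="feature_id")

        self._run("train-ae", [model_dir / "model.json", latent_path], fn)

    def subtype(self) -> None:
        s = self.cfg["subtype"]
        d = self.out
        outputs = [d / "subtypes.tsv", d / "screen.tsv", d / "selection.json"]

        def fn():
            latent = _io.read_omics(d / "latent.tsv").T  # samples x features
            clinical = _io.read_clinical(d / "prep" / "clinical.tsv")
            screen = _subtype.cox_screen(latent, clinical, alpha=s["alpha"])
            screen.to_csv(d / "screen.tsv", sep="\t", index=False,
                          float_format=_io.FLOAT_FORMAT)
            kept = latent.loc[:, screen["selected"].to_numpy()]
            sel = _subtype.kmeans_select(
                kept, k_min=s["k_min"], k_max=s["k_max"],
                seed=stage_seed(self.cfg["seed"], "subtype"))
            result = _subtype.name_subtypes(sel, clinical)
            result.labels.rename("subtype").to_csv(d / "subtypes.tsv", sep="\t")
            _write_json(
                {"chosen_k": sel.chosen_k,
                 "scores": sel.scores.round(6).to_dict(orient="index")},
                d / "selection.json")

        self._run("subtype", outputs, fn)

    def classify(self) -> None:
        c = self.cfg["classify"]
        d = self.out
        outputs = [d / "cv_report.json", d / "predictions.tsv"]

        def fn():
            omics = {name: _io.read_omics(d / "prep" / f"{name}_scaled.tsv")
                     for name in ("expr", "meth")}
            clinical = _io.read_clinical(d / "prep" / "clinical.tsv")
            labels = pd.read_csv(d / "subtypes.tsv", sep="\t",
                                 index_col=0)["subtype"]
            labels.index = labels.index.astype(str)
            report = _classify.crossvalidate(
                omics, clinical, labels, n_splits=c["n_splits"],
                train_fraction=c["train_fraction"],
                seed=stage_seed(self.cfg["seed"], "classify"),
                top_k=c["top_k"], svm_params=c["svm"])
            _write_json(
                {"tag": report.tag, "aggregate": report.aggregate,
                 "per_fold": report.per_fold.round(6).to_dict(orient="records")},
                d / "cv_report.json")
            clf = _classify.SubtypeClassifier(
                top_k=c["top_k"],
                random_state=stage_seed(self.cfg["seed"], "classify"), **c["svm"])
            clf.fit(omics, labels)
            pd.DataFrame(
                {"subtype": clf.predict(omics),
                 "risk": clf.risk_score(omics)},
                index=labels.index,
            ).to_csv(d / "predictions.tsv", sep="\t",
                     float_format=_io.FLOAT_FORMAT, index_label="sample_id")

        self._run("classify", outputs, fn)

    def evaluate(self) -> None:
        d = self.out
        outputs = [d / "covariates.tsv", d / "cox_models.tsv", d / "eval_report.json"]

        def fn():
            clinical = _io.read_clinical(d / "prep" / "clinical.tsv")
            labels = pd.read_csv(d / "subtypes.tsv", sep="\t", index_col=0)["subtype"]
            labels.index = labels.index.astype(str)
            cov = _metrics.covariate_tests(labels, clinical)
            cov.to_csv(d / "covariates.tsv", sep="\t", index=False,
                       float_format=_io.FLOAT_FORMAT)
            base = [c for c in ("age", "gender", "grade", "tumor_type")
                    if c in clinical.columns]
            models = _metrics.cox_compare(
                clinical, labels,
                [base + ["subtype"], ["subtype"],
                 ["tumor_type"] if "tumor_type" in clinical.columns else ["subtype"]])
            models.to_csv(d / "cox_models.tsv", sep="\t", index=False,
                          float_format=_io.FLOAT_FORMAT)
            stat, p = _metrics.logrank_test(
                labels.loc[clinical.index], clinical["time"], clinical["event"])
            _write_json({"logrank_chi2": stat, "logrank_p": p}, d / "eval_report.json")

        self._run("evaluate", outputs, fn)

    def drivers(self) -> None:
        dr = self.cfg["drivers"]
        en = self.cfg["enrich"]
        d = self.out
        outputs = [d / "drivers.tsv"]
        if en["gmt"]:
            outputs.append(d / "enrichment.tsv")

        def fn():
            paths = self._data_paths()
            expr = _io.read_omics(paths["expr"])
            meth = _io.read_omics(paths["meth"])
            labels = pd.read_csv(d / "subtypes.tsv", sep="\t", index_col=0)["subtype"]
            labels.index = labels.index.astype(str)
            res = _drivers.find_driver_genes(
                expr, meth, labels,
                r_threshold=dr["r_threshold"], p_threshold=dr["p_threshold"])
            res.to_csv(d / "drivers.tsv", sep="\t", index=False,
                       float_format=_io.FLOAT_FORMAT)
            if en["gmt"]:
                universe = [g for g in expr.index if g in set(meth.index)]
                query = res.loc[res["direction"] != "none", "gene"]
                enr = _drivers.hypergeom_enrichment(
                    query, _drivers.read_gmt(en["gmt"]), universe,
                    alpha=en["alpha"])
                enr.to_csv(d / "enrichment.tsv", sep="\t", index=False,
                           float_format=_io.FLOAT_FORMAT)

        self._run("drivers", outputs, fn)

    # -- entry point -----------------------------------------------------

    def run(self, stages=None) -> dict:
        plan = stages or STAGES
        for name in plan:
            getattr(self, name.replace("-", "_"))()
        self.manifest["finished_at"] = _time.strftime("%Y-%m-%dT%H:%M:%S")
        _write_json(self.manifest, self.out / "manifest.json")
        return self.manifest


def run_pipeline(config, force: bool = False, stages=None) -> dict:
    """Execute the pipeline described by a config path/dict; returns the
    run manifest (also written to ``<outdir>/manifest.json``)."""
    return PipelineRunner(config, force=force).run(stages=stages)


def output_digests(manifest: dict) -> dict[str, str]:
    """Flatten a manifest into {relative path: sha256} over all stages."""
    out = {}
    root = str(Path(manifest["config"]["outdir"]))
    for stage in manifest["stages"].values():
        for path, digest in stage["outputs"].items():
            rel = str(Path(path)).removeprefix(root).lstrip("/")
            out[rel] = digest
    return out
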