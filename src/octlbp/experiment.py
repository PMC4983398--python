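"""Experiment configuration and full-pipeline orchestration.

An experiment sweeps combinations of preprocessing chain, LBP feature and
(P, R) preset, mapping, representation and classifier over one cohort, runs
LOPO evaluation for each combination, and collects SE/SP/ACC/F1 into a
results table (one CSV row per configuration).  Every randomized component
is seeded deterministically from the single global seed, so a rerun of the
same config reproduces the table exactly.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as vio
from .classify_eval import (
    ClassifierSpec,
    EvalReport,
    RepresentationSpec,
    VolumeFeatures,
    config_fingerprint,
    evaluate,
)
from .lbp import LBPParams, lbp_maps_per_slice, lbp_top_maps
from .phantom import LesionSpec, PhantomSpec, generate_dataset
from .preprocess import (
    NLMParams,
    align_volume,
    denoise_nlm,
    estimate_flatten_model,
    flatten_volume,
)
from .represent import MappingSpec, partition
from .volume import OCTVolume

__all__ = [
    "ExperimentConfig",
    "apply_preprocessing",
    "extract_features",
    "run_experiment",
    "load_config",
    "save_config",
]

log = logging.getLogger("octlbp")


@dataclass
class ExperimentConfig:
    """Declarative description of one experiment sweep.

    ``dataset`` either points at a directory of volumes (``{"path": ...}``
    with a ``labels.csv`` of patient_id,label) or requests a phantom cohort
    (``{"phantom": {"n_per_class": ..., "shape": [...], ...}}``).
    """

    seed: int = 0
    dataset: dict = field(default_factory=lambda: {"phantom": {"n_per_class": 4}})
    preprocessing: list[list[str]] = field(default_factory=lambda: [["nlm"]])
    features: list[dict] = field(
        default_factory=lambda: [{"feature": "lbp", "P": 8, "R": 1}]
    )
    mapping: dict = field(default_factory=lambda: {"mode": "local", "m": 7})
    representation: dict = field(
        default_factory=lambda: {"kind": "bow", "k": 70, "build": "kmeans"}
    )
    classifiers: list[str] = field(default_factory=lambda: ["svm_rbf"])
    nlm: dict = field(default_factory=dict)
    reference_row: int | None = None
    output_dir: str | None = None

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        return cls(**d)


def load_config(path: str | Path) -> ExperimentConfig:
    with open(path) as fh:
        return ExperimentConfig.from_dict(yaml.safe_load(fh))


def save_config(config: ExperimentConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def apply_preprocessing(
    volume: OCTVolume,
    steps: list[str],
    nlm: NLMParams | None = None,
    reference_row: int | None = None,
) -> OCTVolume:
    """Apply an ordered preprocessing chain to one volume.

    Recognized steps: ``nlm``, ``flatten``, ``align``.  Curve estimation for
    flattening runs on the current pipeline state (i.e. after NLM when NLM
    precedes it).  ``flatten`` followed by ``align`` is realized as a single
    warp to the shared reference altitude.
    """
    unknown = set(steps) - {"nlm", "flatten", "align"}
    if unknown:
        raise ValueError(f"unknown preprocessing steps: {sorted(unknown)}")
    out = volume
    if "nlm" in steps:
        out = denoise_nlm(out, nlm)
    if "align" in steps:
        model = estimate_flatten_model(out, reference_row=reference_row)
        out = align_volume(out, model)
    elif "flatten" in steps:
        model = estimate_flatten_model(out, reference_row=reference_row)
        out = flatten_volume(out, model)
    return out


def extract_features(
    volumes: list[OCTVolume],
    feature: str,
    params: LBPParams,
    mapping: MappingSpec,
) -> list[VolumeFeatures]:
    """Compute per-volume element histograms for one (feature, mapping)."""
    out = []
    for vol in volumes:
        if feature == "lbp":
            maps = lbp_maps_per_slice(vol.voxels, params)
        elif feature == "lbptop":
            maps = lbp_top_maps(vol.voxels, params)
        else:
            raise ValueError(f"unknown feature {feature!r}")
        out.append(
            VolumeFeatures(
                patient_id=vol.patient_id,
                label=vol.label,
                elements=partition(maps, mapping),
            )
        )
    return out


def _load_cohort(config: ExperimentConfig) -> list[OCTVolume]:
    ds = config.dataset
    if "phantom" in ds:
        ph = dict(ds["phantom"])
        n_per_class = int(ph.pop("n_per_class", 4))
        if "shape" in ph:
            ph["shape"] = tuple(ph["shape"])
        if "lesion" in ph:
            ph["lesion"] = LesionSpec(**ph["lesion"])
        spec = PhantomSpec(**ph)
        return [vol for vol, _ in generate_dataset(spec, n_per_class, config.seed)]
    root = Path(ds["path"])
    labels = pd.read_csv(root / "labels.csv").set_index("patient_id")["label"]
    vols = []
    for pid, label in labels.items():
        vol = vio.read_volume(root / f"{pid}.tiff", patient_id=str(pid))
        vol.label = str(label)
        vols.append(vol)
    return vols


def run_experiment(config: ExperimentConfig) -> pd.DataFrame:
    """Execute the full sweep; returns the results table.

    One row per (preprocessing x feature x classifier) combination with the
    pooled LOPO metrics.  A failing combination is logged and recorded with
    ``status="failed"`` without aborting the sweep.  When
    ``config.output_dir`` is set, the table is written there as
    ``results.csv`` together with the resolved config.
    """
    t0 = time.time()
    nlm = NLMParams(**config.nlm) if config.nlm else None
    mapping = MappingSpec(**config.mapping)
    rep = RepresentationSpec(**config.representation)
    rows = []
    reports: list[EvalReport] = []
    try:
        cohort = _load_cohort(config)
    except Exception as err:  # noqa: BLE001 - record, don't crash the sweep
        log.error("cohort load failed: %s", err)
        for steps in config.preprocessing:
            for fdict in config.features:
                for clf in config.classifiers:
                    rows.append(_row(steps, fdict, mapping, rep, clf, None, str(err)))
        return pd.DataFrame(rows)
    log.info("cohort loaded: %d volumes (%.1fs)", len(cohort), time.time() - t0)
    for steps in config.preprocessing:
        t0 = time.time()
        try:
            pre = [
                apply_preprocessing(v, steps, nlm, config.reference_row)
                for v in cohort
            ]
        except Exception as err:  # noqa: BLE001 - sweep must survive
            log.error("preprocessing %s failed: %s", steps, err)
            for fdict in config.features:
                for clf in config.classifiers:
                    rows.append(
                        _row(steps, fdict, mapping, rep, clf, None, str(err))
                    )
            continue
        log.info("preprocessing %s done (%.1fs)", "+".join(steps), time.time() - t0)
        for fdict in config.features:
            params = LBPParams(P=int(fdict["P"]), R=int(fdict["R"]))
            t0 = time.time()
            try:
                feats = extract_features(pre, fdict["feature"], params, mapping)
            except Exception as err:  # noqa: BLE001
                log.error("feature %s failed: %s", fdict, err)
                for clf in config.classifiers:
                    rows.append(_row(steps, fdict, mapping, rep, clf, None, str(err)))
                continue
            log.info(
                "features %s (P=%d, R=%d) done (%.1fs)",
                fdict["feature"], params.P, params.R, time.time() - t0,
            )
            for clf_name in config.classifiers:
                t0 = time.time()
                try:
                    spec = ClassifierSpec(family=clf_name, seed=config.seed)
                    report = evaluate(feats, spec, rep, seed=config.seed)
                    reports.append(report)
                    rows.append(_row(steps, fdict, mapping, rep, clf_name, report))
                    log.info(
                        "%s: SE=%.3f SP=%.3f (%.1fs)",
                        clf_name, report.metrics.se, report.metrics.sp,
                        time.time() - t0,
                    )
                except Exception as err:  # noqa: BLE001
                    log.error("classifier %s failed: %s", clf_name, err)
                    rows.append(_row(steps, fdict, mapping, rep, clf_name, None, str(err)))
    table = pd.DataFrame(rows)
    if config.output_dir:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "results.csv", index=False)
        save_config(config, outdir / "config.yaml")
    return table


def _row(
    steps: list[str],
    fdict: dict,
    mapping: MappingSpec,
    rep: RepresentationSpec,
    clf_name: str,
    report: EvalReport | None,
    error: str | None = None,
) -> dict:
    row = {
        "preprocessing": "+".join(steps) if steps else "none",
        "feature": fdict["feature"],
        "P": fdict["P"],
        "R": fdict["R"],
        "mapping": mapping.mode,
        "representation": rep.kind,
        "k": rep.k if rep.kind == "bow" else None,
        "classifier": clf_name,
        "status": "ok" if report else "failed",
        "SE": report.metrics.se if report else None,
        "SP": report.metrics.sp if report else None,
        "ACC": report.metrics.acc if report else None,
        "F1": report.metrics.f1 if report else None,
        "fingerprint": report.config_fingerprint
        if report
        else config_fingerprint({"error": error}),
    }
    if error:
        row["error"] = error
    return row
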