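"""Study orchestration: parameterization, layer-wise and jitter-variance experiments.

The three-stage procedure:

1. *Training* -- a fixed-size hierarchy learns its S2 prototype dictionary
   (unsupervised) from the cross-fin training set, and a linear readout is
   trained on each tap point's features.
2. *Parameterization* -- the C2 readout must classify the non-illusory
   control (CTL) arrow set above an accuracy criterion (85 % correct); if it
   fails, the S2 dictionary is enlarged and training repeats.
3. *Illusion classification* -- Müller-Lyer test sets (20 and 40 deg fins)
   are classified, decisions are aggregated per length difference, and
   cumulative-Gaussian fits yield per-run PSE and JND.

Experiment 1 applies the readout after every layer (input, S1, C1, S2, C2)
under horizontal+vertical (HV) jitter.  Experiment 2 compares C2
classification under HV versus vertical-only (V) jitter.  Runs differ by
regenerated test images and (by default) a resampled prototype dictionary;
a master seed fans out deterministically to every random stage.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import stimuli
from .hmax import HMAX, HMAXConfig, LAYERS, learn_dictionary, s2_respond, c2_pool
from .psychometrics import (CumulativeGaussianModel, ConditionSummary,
                            summarize_condition)
from .readout import VectorizeConfig, classify, percent_correct, train_classifier, vectorize

__all__ = ["ExperimentConfig", "ExperimentResult", "ParameterizationRecord",
           "scale_profile", "parameterize", "parameterization_accuracy",
           "run_experiment1", "run_experiment2", "run_study", "StudyResult"]

ML_KINDS = {20: "ml20", 40: "ml40"}


@dataclass
class ExperimentConfig:
    """Study conditions; defaults are the full-scale ones.

    Counts are per category (training, CTL parameterization) or per
    (length-increment, category) condition (test sets).  ``scale`` tags
    down-scaled profiles produced by :func:`scale_profile`.
    """

    n_train_per_category: int = 500
    n_ctl_param_per_category: int = 200
    n_test_per_delta_c2: int = 200
    n_test_per_delta_other: int = 100
    deltas: tuple = (10, 20, 30, 40, 50, 60)
    angles: tuple = (20, 40)
    n_runs: int = 10
    criterion: float = 85.0
    s2_sizes: tuple = (1000, 2000, 4000)
    resample_dictionary: bool = True
    ridge_alpha: float = 1.0
    hmax: HMAXConfig = field(default_factory=HMAXConfig)
    vectorize: VectorizeConfig = field(default_factory=VectorizeConfig)
    scale: float = 1.0

    def __post_init__(self):
        if not (50.0 < self.criterion < 100.0):
            raise ValueError("criterion must lie in (50, 100) percent")
        for n in (self.n_train_per_category, self.n_ctl_param_per_category,
                  self.n_test_per_delta_c2, self.n_test_per_delta_other, self.n_runs):
            if n <= 0:
                raise ValueError("all counts must be positive")


def scale_profile(cfg: ExperimentConfig, factor: float) -> ExperimentConfig:
    """Proportionally shrink image counts, prototype count and runs for
    desk-scale work; deltas and fin angles are kept.

    Rule: counts -> round(count * factor) floored at 2; prototypes and S2
    size candidates -> round(n * factor) floored at 8; runs ->
    round(n_runs * factor) floored at 3.  The factor is recorded in
    ``scale`` and tags all outputs.
    """
    if not (0.0 < factor <= 1.0):
        raise ValueError("factor must lie in (0, 1]")
    if factor == 1.0:
        return replace(cfg)

    def cnt(x):
        v = max(2, int(round(x * factor)))
        if v < 2:
            raise ValueError("scaled counts below 2 per condition")
        return v

    protos = max(8, int(round(cfg.hmax.n_prototypes * factor)))
    return replace(
        cfg,
        n_train_per_category=cnt(cfg.n_train_per_category),
        n_ctl_param_per_category=cnt(cfg.n_ctl_param_per_category),
        n_test_per_delta_c2=cnt(cfg.n_test_per_delta_c2),
        n_test_per_delta_other=cnt(cfg.n_test_per_delta_other),
        n_runs=max(3, int(round(cfg.n_runs * factor))),
        s2_sizes=tuple(max(8, int(round(s * factor))) for s in cfg.s2_sizes),
        hmax=replace(cfg.hmax, n_prototypes=protos),
        scale=factor,
    )


def _child_seed(master: int, *tags) -> int:
    """Deterministic named sub-seed below 2**31."""
    ints = [int(master) & 0x7FFFFFFF] + [zlib.crc32(str(t).encode()) for t in tags]
    return int(np.random.SeedSequence(ints).generate_state(1)[0] % (2 ** 31))


# ---------------------------------------------------------------------------
# pipeline engine (caches shared between stages)
# ---------------------------------------------------------------------------

class _Engine:
    """Shared state for one (config, jitter mode, master seed) study arm:
    training set, cached training C1 maps, per-run dictionaries, per-layer
    training features and classifiers."""

    def __init__(self, cfg: ExperimentConfig, jitter_mode: str, master_seed: int):
        self.cfg = cfg
        self.jitter = jitter_mode
        self.master = int(master_seed)
        self.model = HMAX(cfg.hmax)
        self._train_set = None
        self._train_c1 = None
        self._det_train_vecs: dict = {}
        self._dicts: dict = {}
        self._s2c2_train: dict = {}
        self._clfs: dict = {}

    def seed(self, *tags) -> int:
        return _child_seed(self.master, self.jitter, *tags)

    @property
    def train_set(self) -> stimuli.StimulusSet:
        if self._train_set is None:
            self._train_set = stimuli.generate_set(
                "train_cross", self.jitter, self.seed("train-set"),
                n_per_category=self.cfg.n_train_per_category)
        return self._train_set

    @property
    def train_c1(self) -> list:
        if self._train_c1 is None:
            self._train_c1 = [self.model.c1_features(img) for img in self.train_set.images]
        return self._train_c1

    def _train_det_vectors(self, layer: str) -> np.ndarray:
        if layer not in self._det_train_vecs:
            vcfg = self.cfg.vectorize
            if layer == "input":
                vecs = [vectorize(img, "input", vcfg) for img in self.train_set.images]
            elif layer == "s1":
                vecs = [vectorize(self.model.forward(img, upto="s1")["s1"], "s1", vcfg)
                        for img in self.train_set.images]
            else:  # c1
                vecs = [vectorize(c1, "c1", vcfg) for c1 in self.train_c1]
            self._det_train_vecs[layer] = np.stack(vecs)
        return self._det_train_vecs[layer]

    def dictionary(self, run: int):
        key = run if self.cfg.resample_dictionary else 0
        if key not in self._dicts:
            rng = np.random.default_rng(self.seed("dictionary", key))
            self._dicts[key] = learn_dictionary(self.train_c1, self.cfg.hmax, rng)
        return self._dicts[key]

    def _train_s2c2_vectors(self, layer: str, run: int) -> np.ndarray:
        key = (layer, run if self.cfg.resample_dictionary else 0)
        if key not in self._s2c2_train:
            d = self.dictionary(run)
            vcfg = self.cfg.vectorize
            vecs = []
            for c1 in self.train_c1:
                s2 = s2_respond(c1, d)
                out = s2 if layer == "s2" else c2_pool(s2, d)
                vecs.append(vectorize(out, layer, vcfg))
            self._s2c2_train[key] = np.stack(vecs)
        return self._s2c2_train[key]

    def train_vectors(self, layer: str, run: int) -> np.ndarray:
        if layer in ("input", "s1", "c1"):
            return self._train_det_vectors(layer)
        return self._train_s2c2_vectors(layer, run)

    def classifier(self, layer: str, run: int):
        # input/S1/C1 features are deterministic, so their readout is shared
        # across runs; S2/C2 readouts follow the (possibly resampled) dictionary
        key = (layer, 0 if layer in ("input", "s1", "c1")
               else (run if self.cfg.resample_dictionary else 0))
        if key not in self._clfs:
            X = self.train_vectors(layer, run)
            y = list(self.train_set.manifest["category"])
            seed = self.seed("classifier", *key)
            self._clfs[key] = train_classifier(
                X, y, layer_id=layer, alpha=self.cfg.ridge_alpha, seed=seed,
                rng=np.random.default_rng(seed))
        return self._clfs[key]

    def test_vectors(self, sset: stimuli.StimulusSet, layer_rows: dict, run: int) -> dict:
        """Feature matrices per layer for the requested row subsets.

        ``layer_rows`` maps layer id -> sorted array of manifest row indices;
        each image is forwarded once, up to the deepest requested layer.
        """
        vcfg = self.cfg.vectorize
        wanted = {layer: set(map(int, rows)) for layer, rows in layer_rows.items()}
        deepest = max(layer_rows, key=LAYERS.index)
        need_dict = LAYERS.index(deepest) >= LAYERS.index("s2")
        d = self.dictionary(run) if need_dict else None
        store = {layer: {} for layer in layer_rows}
        for i, img in enumerate(sset.images):
            layers_here = [l for l, rows in wanted.items() if i in rows]
            if not layers_here:
                continue
            upto = max(layers_here, key=LAYERS.index)
            out = self.model.forward(img, dictionary=d, upto=upto)
            for l in layers_here:
                src = img if l == "input" else out[l]
                store[l][i] = vectorize(src, l, vcfg)
        return {l: np.stack([store[l][i] for i in sorted(store[l])]) for l in store}


# ---------------------------------------------------------------------------
# parameterization
# ---------------------------------------------------------------------------

@dataclass
class ParameterizationRecord:
    jitter_mode: str
    s2_size: int
    accuracy: float  # percent correct on the CTL parameterization set (mean over reps)
    per_replicate: list

    def as_dict(self) -> dict:
        return {"jitter_mode": self.jitter_mode, "s2_size": self.s2_size,
                "ctl_accuracy": self.accuracy, "per_replicate": list(self.per_replicate)}


def parameterization_accuracy(cfg: ExperimentConfig, jitter_mode: str = "HV",
                              seed: int = 0, run: int = 0,
                              engine: _Engine | None = None) -> float:
    """One replicate of the parameterization stage: train on the cross-fin
    set, classify the CTL set (random length differences) at C2; percent correct."""
    eng = engine or _Engine(cfg, jitter_mode, seed)
    ctl = stimuli.generate_set("ctl", jitter_mode, eng.seed("ctl-param", run),
                               n_per_category=cfg.n_ctl_param_per_category)
    rows = np.arange(len(ctl.images))
    X = eng.test_vectors(ctl, {"c2": rows}, run)["c2"]
    model = eng.classifier("c2", run)
    return percent_correct(model, X, list(ctl.manifest["category"]))


def parameterize(cfg: ExperimentConfig, jitter_mode: str = "HV", seed: int = 0,
                 n_replicates: int = 1) -> ParameterizationRecord:
    """Find the smallest candidate S2 size whose mean CTL accuracy meets the
    criterion; raises if none does."""
    if list(cfg.s2_sizes) != sorted(cfg.s2_sizes):
        raise ValueError("s2_sizes must be ascending")
    attempts = []
    for size in cfg.s2_sizes:
        trial = replace(cfg, hmax=replace(cfg.hmax, n_prototypes=size))
        eng = _Engine(trial, jitter_mode, seed)
        accs = [parameterization_accuracy(trial, jitter_mode, seed, run=r, engine=eng)
                for r in range(n_replicates)]
        mean_acc = float(np.mean(accs))
        attempts.append((size, mean_acc))
        if mean_acc > cfg.criterion:
            return ParameterizationRecord(jitter_mode, size, mean_acc, accs)
    raise RuntimeError(
        f"CTL accuracy stayed at/below the {cfg.criterion}% criterion for every "
        f"candidate S2 size; attempts: {attempts}")


# ---------------------------------------------------------------------------
# experiments
# ---------------------------------------------------------------------------

@dataclass
class ExperimentResult:
    """Per-condition summaries (+ fits) for one experiment."""

    experiment: str
    summaries: list
    parameterization: dict
    config: ExperimentConfig
    fits: dict = field(default_factory=dict, repr=False)

    def table(self) -> pd.DataFrame:
        df = pd.DataFrame([s.as_row() for s in self.summaries])
        df["scaled_down"] = self.config.scale < 1.0
        df["scale"] = self.config.scale
        return df

    def get(self, **cond) -> ConditionSummary:
        for s in self.summaries:
            if all(s.condition.get(k) == v for k, v in cond.items()):
                return s
        raise KeyError(f"no condition matching {cond}")

    def summary(self) -> str:
        with pd.option_context("display.width", 120):
            return (f"{self.experiment}: per-condition PSE/JND "
                    f"(mean +/- s.e.m. over accepted runs)\n" + self.table().to_string())


def _subset_rows(manifest: pd.DataFrame, n_per_condition: int) -> np.ndarray:
    """First n rows of every (delta, category) cell, in manifest order."""
    idx = (manifest.groupby(["delta", "category"], sort=False)
           .head(n_per_condition).index.to_numpy())
    return np.sort(idx)


def _fit_predictions(manifest: pd.DataFrame, rows: np.ndarray, labels) :
    df = pd.DataFrame({"delta": manifest["delta"].to_numpy()[rows], "predicted": labels})
    return CumulativeGaussianModel.from_predictions(df).fit()


def run_experiment1(cfg: ExperimentConfig, seed: int = 0,
                    layers=LAYERS, engine: _Engine | None = None) -> ExperimentResult:
    """Layer-wise illusion classification under HV jitter.

    For each run and fin angle, one Müller-Lyer test set (C2-sized counts)
    is generated; the C2 readout sees all of it and the other layers the
    leading ``n_test_per_delta_other`` images per condition, mirroring the
    larger final-layer test set.  Returns one ConditionSummary per
    (layer, angle).
    """
    eng = engine or _Engine(cfg, "HV", seed)
    layers = [l for l in LAYERS if l in layers]
    fits = {(l, a): [] for l in layers for a in cfg.angles}
    for run in range(cfg.n_runs):
        for angle in cfg.angles:
            kind = ML_KINDS[angle]
            sset = stimuli.generate_set(
                kind, "HV", eng.seed("test", kind, run),
                deltas=cfg.deltas, n_per_condition=cfg.n_test_per_delta_c2)
            all_rows = np.arange(len(sset.images))
            sub = _subset_rows(sset.manifest, cfg.n_test_per_delta_other)
            layer_rows = {l: (all_rows if l == "c2" else sub) for l in layers}
            feats = eng.test_vectors(sset, layer_rows, run)
            for l in layers:
                pred, _ = classify(eng.classifier(l, run), feats[l])
                fits[(l, angle)].append(
                    _fit_predictions(sset.manifest, layer_rows[l], pred))
    summaries = [
        summarize_condition(v, condition={
            "experiment": "exp1", "layer": l, "set_kind": ML_KINDS[a],
            "jitter_mode": "HV", "fin_angle": a})
        for (l, a), v in fits.items()]
    return ExperimentResult("exp1", summaries, {}, cfg, fits={
        f"{l}/{a}": v for (l, a), v in fits.items()})


def run_experiment2(cfg: ExperimentConfig, seed: int = 0,
                    reuse_summaries: dict | None = None,
                    engines: dict | None = None) -> ExperimentResult:
    """C2 classification of CTL and Müller-Lyer sets under HV versus V jitter.

    ``reuse_summaries`` may supply already-computed summaries keyed by
    (set_kind, jitter_mode) -- e.g. the HV Müller-Lyer rows of Experiment 1
    -- to avoid recomputation; missing cells are computed here.
    """
    reuse = dict(reuse_summaries or {})
    engines = engines or {}
    set_kinds = ["ctl"] + [ML_KINDS[a] for a in cfg.angles]
    summaries, fits_out = [], {}
    for jitter in ("HV", "V"):
        eng = engines.get(jitter) or _Engine(cfg, jitter, seed)
        engines[jitter] = eng
        for kind in set_kinds:
            cond = {"experiment": "exp2", "layer": "c2", "set_kind": kind,
                    "jitter_mode": jitter,
                    "fin_angle": {"ml20": 20, "ml40": 40}.get(kind)}
            if (kind, jitter) in reuse:
                prior = reuse[(kind, jitter)]
                summaries.append(ConditionSummary(cond, list(prior.pses),
                                                  list(prior.jnds), prior.n_discarded))
                continue
            run_fits = []
            for run in range(cfg.n_runs):
                sset = stimuli.generate_set(
                    kind, jitter, eng.seed("test", kind, run),
                    deltas=cfg.deltas, n_per_condition=cfg.n_test_per_delta_c2)
                rows = np.arange(len(sset.images))
                X = eng.test_vectors(sset, {"c2": rows}, run)["c2"]
                pred, _ = classify(eng.classifier("c2", run), X)
                run_fits.append(_fit_predictions(sset.manifest, rows, pred))
            summaries.append(summarize_condition(run_fits, condition=cond))
            fits_out[f"{kind}/{jitter}"] = run_fits
    return ExperimentResult("exp2", summaries, {}, cfg, fits=fits_out)


@dataclass
class StudyResult:
    parameterization: dict
    exp1: ExperimentResult
    exp2: ExperimentResult

    def table(self) -> pd.DataFrame:
        return pd.concat([self.exp1.table(), self.exp2.table()], ignore_index=True)


def run_study(cfg: ExperimentConfig, seed: int = 0,
              n_param_replicates: int = 3) -> StudyResult:
    """Full procedure: per-jitter parameterization, Experiment 1 (HV, all
    layers) and Experiment 2 (C2, HV vs V; HV Müller-Lyer rows reused from
    Experiment 1)."""
    engines = {j: _Engine(cfg, j, seed) for j in ("HV", "V")}
    param = {}
    for jitter in ("HV", "V"):
        accs = [parameterization_accuracy(cfg, jitter, seed, run=r, engine=engines[jitter])
                for r in range(n_param_replicates)]
        param[jitter] = ParameterizationRecord(
            jitter, cfg.hmax.n_prototypes, float(np.mean(accs)), accs)
        if param[jitter].accuracy <= cfg.criterion:
            param[jitter].per_replicate = accs  # recorded even when short of criterion

    exp1 = run_experiment1(cfg, seed, engine=engines["HV"])
    reuse = {}
    for a in cfg.angles:
        s = exp1.get(layer="c2", fin_angle=a)
        reuse[(ML_KINDS[a], "HV")] = s
    exp2 = run_experiment2(cfg, seed, reuse_summaries=reuse, engines=engines)
    exp1.parameterization = {"HV": param["HV"].as_dict()}
    exp2.parameterization = {j: p.as_dict() for j, p in param.items()}
    return StudyResult({j: p.as_dict() for j, p in param.items()}, exp1, exp2)
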