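"""Post hoc random-forest variant quality calibration.

Raw pipeline output has poor precision if every candidate is emitted and the
generative model's token probabilities are not calibrated variant qualities.
A random forest (100 trees, depth 25) is trained to separate true from false
raw calls; its true-call probability becomes the phred-scaled QUAL via
``-10 log10(1 - p)`` (capped at 100), so filtering at Q10 keeps calls with
p >= 0.9.
"""

from __future__ import annotations

import math
import pickle
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .variants import VariantCall, Variant

MAX_PHRED = 100.0

#: ordered feature schema; scoring validates against the fitted schema
FEATURE_SCHEMA = (
    "window_count",
    "window_fraction",
    "n_cis",
    "n_trans",
    "min_kmer_prob",
    "mean_kmer_prob",
    "mean_window_offset",
    "genotype_vote_entropy",
    "depth",
    "alt_support",
    "is_indel",
    "allele_length_delta",
)


def _vote_entropy(het: int, hom: int) -> float:
    n = het + hom
    if n == 0:
        return 0.0
    h = 0.0
    for k in (het, hom):
        if k:
            p = k / n
            h -= p * math.log2(p)
    return h


def call_features(call: VariantCall) -> np.ndarray:
    f = call.features
    frac = f.window_count / f.total_windows if f.total_windows else 0.0
    return np.array([
        f.window_count,
        frac,
        f.n_cis,
        f.n_trans,
        f.min_kmer_prob,
        f.mean_kmer_prob,
        f.mean_window_offset,
        _vote_entropy(f.het_votes, f.hom_votes),
        f.depth,
        f.alt_support,
        0.0 if call.variant.is_snv else 1.0,
        call.variant.size_change,
    ], dtype=np.float64)


def prob_to_phred(p: float) -> float:
    """Phred-scale a true-call probability, capped at Q100."""
    p = min(max(float(p), 0.0), 1.0)
    if p >= 1.0 - 10 ** (-MAX_PHRED / 10):
        return MAX_PHRED
    return -10.0 * math.log10(1.0 - p)


def build_training_set(raw_calls: list[VariantCall],
                       truth: list[tuple[Variant, str]],
                       confident_bed: list[tuple[str, int, int]] | None = None
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Label raw calls TP/FP against truth and expand features.

    A call is TP only when position, alleles AND genotype match the truth
    record (a correct allele with the wrong genotype trains as FP — the
    strictest reading; the evaluation module reports such calls separately).
    Calls outside the confident regions are dropped.
    """
    from .evaluation import genotypes_equivalent

    truth_by_key = {v.key(): gt for v, gt in truth}
    feats, labels = [], []
    for call in raw_calls:
        v = call.variant
        if confident_bed is not None and not any(
                c == v.chrom and s <= v.pos < e for c, s, e in confident_bed):
            continue
        gt = truth_by_key.get(v.key())
        tp = gt is not None and genotypes_equivalent(call.genotype, gt)
        feats.append(call_features(call))
        labels.append(1 if tp else 0)
    if not feats:
        return np.empty((0, len(FEATURE_SCHEMA))), np.empty(0, dtype=int)
    return np.vstack(feats), np.asarray(labels, dtype=int)


class VariantQualityModel:
    """sklearn-style wrapper: ``fit(X, y)`` / ``predict_proba`` plus
    call-level ``score`` used by the pipeline.

    Parameters mirror the calibration forest: 100 trees, maximum depth 25,
    balanced class weights.
    """

    def __init__(self, n_estimators: int = 100, max_depth: int = 25,
                 seed: int = 0):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.seed = seed
        self.feature_schema = FEATURE_SCHEMA

    def get_params(self, deep: bool = True) -> dict:
        return {"n_estimators": self.n_estimators,
                "max_depth": self.max_depth, "seed": self.seed}

    def set_params(self, **params) -> "VariantQualityModel":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X: np.ndarray, y: np.ndarray) -> "VariantQualityModel":
        X = np.asarray(X)
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError(
                "calibration needs both true- and false-positive calls; "
                f"got only class {classes.tolist()}")
        if X.shape[1] != len(self.feature_schema):
            raise ValueError("feature table does not match the schema")
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_estimators, max_depth=self.max_depth,
            class_weight="balanced", random_state=self.seed)
        self.forest_.fit(X, y)
        self.fitted_schema_ = self.feature_schema
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        self._check_fitted()
        return self.forest_.predict_proba(np.asarray(X))

    def score_features(self, x: np.ndarray) -> float:
        proba = self.predict_proba(np.asarray(x).reshape(1, -1))[0]
        idx = list(self.forest_.classes_).index(1)
        return float(proba[idx])

    def score(self, call: VariantCall) -> float:
        """True-call probability for one variant call."""
        x = call_features(call)
        if len(x) != len(self.fitted_schema_):
            raise ValueError("call features do not match the fitted schema")
        return self.score_features(x)

    @staticmethod
    def prob_to_phred(p: float) -> float:
        return prob_to_phred(p)

    def _check_fitted(self) -> None:
        if not hasattr(self, "forest_"):
            raise ValueError("classifier is not fitted")

    # ---- persistence --------------------------------------------------
    def save(self, path: str) -> None:
        self._check_fitted()
        with open(path, "wb") as fh:
            pickle.dump({"version": 1, "params": self.get_params(),
                         "schema": self.fitted_schema_,
                         "forest": self.forest_}, fh)

    @classmethod
    def load(cls, path: str) -> "VariantQualityModel":
        with open(path, "rb") as fh:
            blob = pickle.load(fh)
        model = cls(**blob["params"])
        model.forest_ = blob["forest"]
        model.fitted_schema_ = tuple(blob["schema"])
        return model


def fit_classifier(raw_calls: list[VariantCall],
                   truth: list[tuple[Variant, str]],
                   confident_bed=None, seed: int = 0) -> VariantQualityModel:
    X, y = build_training_set(raw_calls, truth, confident_bed)
    return VariantQualityModel(seed=seed).fit(X, y)
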