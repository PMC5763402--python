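"""Data model for randomized-trial survival datasets with biomarkers.

A `TrialDataset` holds an n x p biomarker matrix, a treatment arm code in
{-0.5, +0.5} (+0.5 = experimental arm), observed survival times in years and
event indicators, plus optional ground-truth labels when the data were
simulated.  `build_design` materializes the interaction design matrices the
selection strategies work on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "TrialDataset", "TruthLabels", "InteractionDesign", "Scaler",
    "standardize", "build_design", "read_trial_csv", "write_trial_csv",
]

ARM_CODES = (-0.5, 0.5)


@dataclass
class TruthLabels:
    """Ground truth of a simulated dataset.

    modifiers : indices i with a true biomarker-by-treatment interaction
        (gamma_i != 0); prognostic_only : indices with beta_i != 0 and
        gamma_i == 0.
    """

    modifiers: np.ndarray
    prognostic_only: np.ndarray
    true_gamma: np.ndarray
    true_beta: np.ndarray

    def __post_init__(self):
        self.modifiers = np.asarray(self.modifiers, dtype=int)
        self.prognostic_only = np.asarray(self.prognostic_only, dtype=int)
        self.true_gamma = np.asarray(self.true_gamma, dtype=float)
        self.true_beta = np.asarray(self.true_beta, dtype=float)
        if np.intersect1d(self.modifiers, self.prognostic_only).size:
            raise ValueError("modifiers and prognostic_only must be disjoint")
        p = self.true_gamma.size
        for idx in (self.modifiers, self.prognostic_only):
            if idx.size and (idx.min() < 0 or idx.max() >= p):
                raise ValueError("truth indices out of range")

    def to_json(self) -> str:
        return json.dumps({
            "modifiers": self.modifiers.tolist(),
            "prognostic_only": self.prognostic_only.tolist(),
            "true_gamma": self.true_gamma.tolist(),
            "true_beta": self.true_beta.tolist(),
        })

    @classmethod
    def from_json(cls, s: str) -> "TruthLabels":
        d = json.loads(s)
        return cls(np.array(d["modifiers"], int), np.array(d["prognostic_only"], int),
                   np.array(d["true_gamma"], float), np.array(d["true_beta"], float))


@dataclass
class TrialDataset:
    X: np.ndarray
    treatment: np.ndarray
    time: np.ndarray
    event: np.ndarray
    biomarker_ids: list[str] | None = None
    truth: TruthLabels | None = None

    def __post_init__(self):
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.treatment = np.asarray(self.treatment, dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=float)
        n = self.X.shape[0]
        if n < 2:
            raise ValueError("need at least two patients")
        for name, v in (("treatment", self.treatment), ("time", self.time),
                        ("event", self.event)):
            if v.shape != (n,):
                raise ValueError(f"{name} must have length n={n}")
        if not np.all(np.isin(self.treatment, ARM_CODES)):
            raise ValueError("treatment codes must be -0.5 (control) or +0.5 (experimental)")
        if np.any(self.time <= 0):
            raise ValueError("all survival times must be positive")
        if not np.all(np.isin(self.event, (0.0, 1.0))):
            raise ValueError("event must be binary 0/1")
        if self.event.sum() < 1:
            raise ValueError("at least one event is required")
        if self.biomarker_ids is None:
            self.biomarker_ids = [f"bm{i + 1:04d}" for i in range(self.p)]
        elif len(self.biomarker_ids) != self.p:
            raise ValueError("biomarker_ids length must equal p")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


@dataclass
class Scaler:
    """Column means/sds learned on a training set (sd uses ddof=1)."""

    mean: np.ndarray
    sd: np.ndarray

    def apply(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.sd


def standardize(dataset: TrialDataset, scaler: Scaler | None = None):
    """Z-score the biomarker columns; treatment/time/event untouched.

    Returns (standardized dataset, scaler).  Pass a training `scaler` to
    transform validation data with the training means/sds (whose columns then
    generally do not have mean 0).
    """
    X = dataset.X
    if np.any(~np.isfinite(X)):
        raise ValueError("NaN or infinite biomarker values")
    if scaler is None:
        sd = X.std(axis=0, ddof=1)
        bad = np.where(sd <= 0)[0]
        if bad.size:
            names = [dataset.biomarker_ids[i] for i in bad[:5]]
            raise ValueError(f"constant biomarker column(s): {names}")
        scaler = Scaler(mean=X.mean(axis=0), sd=sd)
    return replace(dataset, X=scaler.apply(X)), scaler


@dataclass
class InteractionDesign:
    """Design matrix with labelled columns for the Cox solvers.

    column_roles : per column one of {"treatment", "main", "interaction",
    "component"}; parent_biomarker maps design columns back to biomarker
    indices (-1 for treatment/component columns).
    """

    Z: np.ndarray
    column_roles: list[str]
    parent_biomarker: np.ndarray
    kind: str

    @property
    def interaction_cols(self) -> np.ndarray:
        return np.array([j for j, r in enumerate(self.column_roles)
                         if r == "interaction"], dtype=int)

    @property
    def main_cols(self) -> np.ndarray:
        return np.array([j for j, r in enumerate(self.column_roles)
                         if r == "main"], dtype=int)

    @property
    def treatment_col(self) -> int | None:
        try:
            return self.column_roles.index("treatment")
        except ValueError:
            return None


def build_design(dataset: TrialDataset, kind: str,
                 components: np.ndarray | None = None) -> InteractionDesign:
    """Assemble the design matrix for a given modelling strategy.

    kind:
      - "full":              [T | X | X*T]
      - "interactions_only": [X*T]  (the modified covariates M_i = X_i * T)
      - "two_I":             [T | X*1(T=+0.5) | X*1(T=-0.5)]
      - "pca"/"pls":         [T | Z_1..Z_K | X*T] with `components` as Z
    """
    X, T = dataset.X, dataset.treatment
    p = dataset.p
    XT = X * T[:, None]
    arange = np.arange(p)
    if kind == "full":
        Z = np.hstack([T[:, None], X, XT])
        roles = ["treatment"] + ["main"] * p + ["interaction"] * p
        parent = np.concatenate([[-1], arange, arange])
    elif kind == "interactions_only":
        Z = XT
        roles = ["interaction"] * p
        parent = arange.copy()
    elif kind == "two_I":
        plus = X * (T[:, None] > 0)
        minus = X * (T[:, None] < 0)
        Z = np.hstack([T[:, None], plus, minus])
        roles = ["treatment"] + ["main"] * (2 * p)
        parent = np.concatenate([[-1], arange, arange])
    elif kind in ("pca", "pls"):
        if components is None:
            raise ValueError(f"kind={kind!r} requires a component matrix")
        comp = np.atleast_2d(np.asarray(components, dtype=float))
        if comp.shape[0] != dataset.n:
            raise ValueError("components must have one row per patient")
        K = comp.shape[1]
        Z = np.hstack([T[:, None], comp, XT])
        roles = ["treatment"] + ["component"] * K + ["interaction"] * p
        parent = np.concatenate([[-1], np.full(K, -1), arange])
    else:
        raise ValueError(f"unknown design kind: {kind!r}")
    return InteractionDesign(Z=Z, column_roles=roles,
                             parent_biomarker=parent.astype(int), kind=kind)


# ---------------------------------------------------------------------------
# CSV plumbing
# ---------------------------------------------------------------------------

_MANDATORY = ("time", "event", "treatment")


def read_trial_csv(path, truth_path=None) -> TrialDataset:
    """Read a trial CSV (columns time,event,treatment,<biomarkers...>).

    Treatment accepted as {0,1} or {-0.5,+0.5} and recoded to -0.5/+0.5.
    """
    df = pd.read_csv(path)
    for col in _MANDATORY:
        if col not in df.columns:
            raise ValueError(f"missing mandatory column {col!r}")
    trt = df["treatment"].to_numpy(dtype=float)
    if np.all(np.isin(trt, (0.0, 1.0))):
        trt = trt - 0.5
    bm_cols = [c for c in df.columns if c not in _MANDATORY]
    truth = None
    if truth_path is not None:
        with open(truth_path) as fh:
            truth = TruthLabels.from_json(fh.read())
    return TrialDataset(X=df[bm_cols].to_numpy(dtype=float), treatment=trt,
                        time=df["time"].to_numpy(dtype=float),
                        event=df["event"].to_numpy(dtype=float),
                        biomarker_ids=bm_cols, truth=truth)


def write_trial_csv(dataset: TrialDataset, path, truth_path=None):
    df = pd.DataFrame(dataset.X, columns=dataset.biomarker_ids)
    df.insert(0, "treatment", dataset.treatment)
    df.insert(0, "event", dataset.event.astype(int))
    df.insert(0, "time", dataset.time)
    df.to_csv(path, index=False, float_format="%.17g")
    if truth_path is not None and dataset.truth is not None:
        with open(truth_path, "w") as fh:
            fh.write(dataset.truth.to_json())
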