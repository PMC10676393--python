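"""Core containers: panel data, generative specs, networks, summary tables."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: CES-D-8 item labels, Table-order (two positively worded items included
#: in their raw response direction).
CESD8_ITEMS = (
    "depressed",
    "effort",
    "restless_sleep",
    "happy",
    "lonely",
    "enjoyed_life",
    "sad",
    "get_going",
)

#: Items reverse-coded before forming the 0-8 depression sum score.
REVERSE_CODED = ("happy", "enjoyed_life")

#: Two-factor split of the scale (depressed affect vs somatic complaints).
DEPRESSED_AFFECT = ("depressed", "happy", "lonely", "enjoyed_life", "sad")
SOMATIC_COMPLAINTS = ("effort", "restless_sleep", "get_going")

DEFAULT_COVARIATES = ("gender", "ethnicity_minority")


@dataclass
class GroundTruthSpec:
    """Generative parameters for a cross-lagged logistic symptom process.

    ``B[j, k]`` is the log-odds effect of item ``j`` at wave ``t`` on item
    ``k`` at wave ``t+1``; the diagonal holds the autoregressive paths.
    Intercepts are calibrated so that with ``B = 0`` marginal endorsement
    equals the configured targets (covariate effects integrated out).
    """

    item_labels: tuple[str, ...]
    n_waves: int
    wave1_intercepts: np.ndarray          # (K,) log-odds
    transition_intercepts: np.ndarray     # (K,) log-odds
    B: np.ndarray                         # (K, K) log-odds
    covariate_labels: tuple[str, ...]
    covariate_effects: np.ndarray         # (C, K) log-odds
    covariate_prevalences: np.ndarray     # (C,)
    attrition_intercept: float
    attrition_covariate_coefs: np.ndarray  # (C,)
    attrition_sumscore_coef: float
    seed: int = 0

    def __post_init__(self):
        self.wave1_intercepts = np.asarray(self.wave1_intercepts, dtype=float)
        self.transition_intercepts = np.asarray(self.transition_intercepts, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        self.covariate_effects = np.atleast_2d(np.asarray(self.covariate_effects, dtype=float))
        self.covariate_prevalences = np.asarray(self.covariate_prevalences, dtype=float)
        self.attrition_covariate_coefs = np.asarray(self.attrition_covariate_coefs, dtype=float)
        k = self.n_items
        if self.B.shape != (k, k):
            raise ValueError(f"B must be square {k}x{k}, got {self.B.shape}")
        if not np.all(np.isfinite(self.B)):
            raise ValueError("B must be finite")
        if not (np.all(self.covariate_prevalences > 0) and np.all(self.covariate_prevalences < 1)):
            raise ValueError("covariate prevalences must lie in (0,1)")
        for name, arr in (("wave1_intercepts", self.wave1_intercepts),
                          ("transition_intercepts", self.transition_intercepts)):
            if arr.shape != (k,):
                raise ValueError(f"{name} must have length {k}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} implies probabilities outside (0,1)")
        if self.n_waves < 1:
            raise ValueError("n_waves must be >= 1")

    @property
    def n_items(self) -> int:
        return len(self.item_labels)

    @property
    def n_covariates(self) -> int:
        return len(self.covariate_labels)


@dataclass
class PanelDataset:
    """Subjects x waves x items binary panel with an explicit missingness mask.

    ``items`` holds 0/1 values that are only meaningful where ``observed``
    is True; no numeric sentinel is ever used for missing cells.
    """

    subject_ids: np.ndarray       # (n,)
    items: np.ndarray             # (n, W, K) uint8
    observed: np.ndarray          # (n, W, K) bool
    covariates: np.ndarray        # (n, C) uint8
    item_labels: tuple[str, ...]
    wave_labels: tuple[int, ...]
    covariate_labels: tuple[str, ...]

    def __post_init__(self):
        self.subject_ids = np.asarray(self.subject_ids)
        self.items = np.asarray(self.items, dtype=np.uint8)
        self.observed = np.asarray(self.observed, dtype=bool)
        self.covariates = np.asarray(self.covariates, dtype=np.uint8)
        n, w, k = self.items.shape
        if self.observed.shape != (n, w, k):
            raise ValueError("observed mask must match items shape")
        if len(self.item_labels) != k or len(self.wave_labels) != w:
            raise ValueError("label lengths must match items shape")
        if len(np.unique(self.subject_ids)) != n:
            raise ValueError("subject ids must be unique")
        if self.covariates.shape[0] != n or self.covariates.shape[1] != len(self.covariate_labels):
            raise ValueError("covariates must be n_subjects x n_covariates")
        if self.items[self.observed].size and not np.all(np.isin(self.items[self.observed], (0, 1))):
            raise ValueError("observed item values must be 0/1")

    # -- basic geometry ----------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return self.items.shape[0]

    @property
    def n_waves(self) -> int:
        return self.items.shape[1]

    @property
    def n_items(self) -> int:
        return self.items.shape[2]

    # -- views -------------------------------------------------------------
    def values_float(self) -> np.ndarray:
        """Items as float with NaN where unobserved (pandas interop)."""
        out = self.items.astype(float)
        out[~self.observed] = np.nan
        return out

    def wave_observed(self) -> np.ndarray:
        """(n, W) bool: subject contributed a fully observed item set at wave."""
        return self.observed.all(axis=2)

    def retained_per_wave(self) -> np.ndarray:
        """Subjects with at least one observed item per wave."""
        return self.observed.any(axis=2).sum(axis=0)

    def is_monotone(self) -> bool:
        """True if missingness follows monotone attrition (no returns)."""
        present = self.observed.any(axis=2)
        # once absent, absent ever after
        return not np.any(~present[:, :-1] & present[:, 1:])

    def item_index(self, label: str) -> int:
        return self.item_labels.index(label)

    def copy(self) -> "PanelDataset":
        return replace(
            self,
            subject_ids=self.subject_ids.copy(),
            items=self.items.copy(),
            observed=self.observed.copy(),
            covariates=self.covariates.copy(),
        )


@dataclass
class CLPNetwork:
    """One wave-pair transition model estimated by node-wise lasso logistic.

    Rows of ``coef`` are predictors (items at wave t, then covariates),
    columns are outcome items at wave t+1.  ``scale`` is ``"log_odds"`` or
    ``"or"``; the OR view is the elementwise exponential of the log-odds
    view, so OR 1 marks an absent edge.
    """

    predictor_labels: tuple[str, ...]
    outcome_labels: tuple[str, ...]
    coef: np.ndarray                  # (P, K)
    intercepts: np.ndarray            # (K,)
    penalties: np.ndarray             # (K,) selected per outcome
    n: int
    scale: str = "log_odds"
    covariate_rows: tuple[int, ...] = ()
    label: str = ""
    selection_rule: str = "1se"

    def __post_init__(self):
        self.coef = np.asarray(self.coef, dtype=float)
        self.intercepts = np.asarray(self.intercepts, dtype=float)
        self.penalties = np.asarray(self.penalties, dtype=float)
        if self.coef.shape != (len(self.predictor_labels), len(self.outcome_labels)):
            raise ValueError("coef shape must be (n_predictors, n_outcomes)")
        if self.scale not in ("log_odds", "or"):
            raise ValueError("scale must be 'log_odds' or 'or'")

    @property
    def n_items(self) -> int:
        return len(self.outcome_labels)

    @property
    def item_rows(self) -> np.ndarray:
        return np.setdiff1d(np.arange(self.coef.shape[0]), np.asarray(self.covariate_rows, dtype=int))

    def item_matrix(self) -> np.ndarray:
        """(K, K) item-to-item block (autoregressive diagonal included)."""
        return self.coef[self.item_rows, :]

    def cross_lagged(self) -> np.ndarray:
        """Item block with the autoregressive diagonal zeroed out."""
        m = self.item_matrix().copy()
        np.fill_diagonal(m, 0.0)
        return m


@dataclass
class CentralityTable:
    """Per-item cross-lagged expected influence, raw and z-standardized."""

    item_labels: tuple[str, ...]
    in_ei: np.ndarray
    out_ei: np.ndarray
    in_ei_z: np.ndarray
    out_ei_z: np.ndarray
    network_label: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "in_ei": self.in_ei,
                "out_ei": self.out_ei,
                "in_ei_z": self.in_ei_z,
                "out_ei_z": self.out_ei_z,
            },
            index=pd.Index(self.item_labels, name="item"),
        )


@dataclass
class NetworkComparison:
    """Cross-network consistency: edge replication and correlation statistics."""

    label_a: str
    label_b: str
    replication_pct_first: float
    replication_pct_union: float
    replication_pct_either: float
    edge_weight_r: float
    in_ei_r: float
    out_ei_r: float
    n_edges_a: int
    n_edges_b: int
    n_replicated: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class IsingNetwork:
    """Cross-sectional pairwise binary (Ising) network for one wave."""

    item_labels: tuple[str, ...]
    weights: np.ndarray           # (K, K) symmetric, zero diagonal
    thresholds: np.ndarray        # (K,)
    gamma: float
    rule: str
    label: str = ""
    dropped_items: tuple[str, ...] = ()

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        k = len(self.item_labels)
        if self.weights.shape != (k, k):
            raise ValueError("weights must be square over item labels")
        if not np.allclose(self.weights, self.weights.T):
            raise ValueError("weights must be symmetric")
        if not np.all(np.diag(self.weights) == 0):
            raise ValueError("weights must have zero diagonal")


@dataclass
class MCARTestResult:
    """Little's MCAR test: chi-square statistic over missingness patterns."""

    d2: float
    df: int
    p_value: float
    n_patterns: int


@dataclass
class BootstrapDistribution:
    """Replicate-level CLPN estimates from nonparametric or case-drop resampling."""

    kind: str                       # "nonparametric" | "case-drop"
    n_requested: int
    coefs: np.ndarray               # (B, P, K) log-odds
    in_ei: np.ndarray               # (B, K)
    out_ei: np.ndarray              # (B, K)
    predictor_labels: tuple[str, ...]
    outcome_labels: tuple[str, ...]
    covariate_rows: tuple[int, ...]
    seed: int
    retained_fraction: np.ndarray | None = None   # (B,) case-drop only
    failures: list = field(default_factory=list)

    @property
    def n_completed(self) -> int:
        return self.coefs.shape[0]


@dataclass
class DifferenceTestResult:
    """Pairwise bootstrap difference test over edges or centralities."""

    labels: tuple[str, ...]
    significant: np.ndarray         # (m, m) bool, symmetric, False diagonal
    ci_low: np.ndarray              # (m, m)
    ci_high: np.ndarray             # (m, m)
    alpha: float

    def __post_init__(self):
        if not np.array_equal(self.significant, self.significant.T):
            raise ValueError("significance matrix must be symmetric")


@dataclass
class StabilityResult:
    """Case-drop stability curve and CS-coefficients for centrality indices."""

    proportions: np.ndarray          # drop proportions
    correlations_in: np.ndarray      # (len(proportions), B)
    correlations_out: np.ndarray
    cs_in: float
    cs_out: float
    correlation_type: str = "spearman"

    def curve(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "drop_proportion": self.proportions,
                "mean_corr_in": np.nanmean(self.correlations_in, axis=1),
                "mean_corr_out": np.nanmean(self.correlations_out, axis=1),
            }
        )
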