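"""Factorized linear estimation of rare-disease incidence from session counts.

Intent-classified sessions are aggregated into a (disease, region, season)
panel; incidence — rescaled so the training maximum equals 1 — is then fit
by one of three linear estimator variants:

* ``general``   — one coefficient set shared by every disease and region:
  ``y_hat = a_d * x_sd + a_n * x_sn + b``
* ``spec_d``    — per-disease coefficients ``a_d(i), a_n(i), b(i)``
* ``spec_dl``   — multiplicative disease x region factorization:
  ``y_hat = a_d(i) t_d(j) x_sd + a_n(i) t_n(j) x_sn + b(i) f(j)``

``x_sd``/``x_sn`` are RD-concerned and news-concerned session counts; with
``input_type="query"`` the two session terms are replaced by three raw
query-count terms (name-, gene- and treatment-matched queries), which is
the baseline the session input is compared against.

Fitting minimizes mean squared error with Adam (max 1000 epochs), early
stopping on validation loss; the chronological split is train on the first
two years, validate on the third, test on the fourth.  Metrics are RMSE
and the relative error rate RER = sum|y_hat - y| / sum y.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin

from ._nn import Adam
from .intent_labels import NEWS, RD, as_intent_index
from .lexicon import LEVEL1_CATEGORIES, Lexicon, QuerySet
from .sessions import Session, StudyWindow

__all__ = [
    "SESSION_INPUT_COLS",
    "QUERY_INPUT_COLS",
    "PANEL_COLUMNS",
    "IncidenceScaler",
    "IncidenceRegressor",
    "FitResult",
    "aggregate_panel",
    "split_by_year",
    "fit_variant",
    "rmse",
    "rer",
    "news_weight_products",
    "case_series",
]

SESSION_INPUT_COLS = ("x_sd", "x_sn")
QUERY_INPUT_COLS = ("x_name", "x_gene", "x_treat")
PANEL_COLUMNS = ("disease", "region", "period") + SESSION_INPUT_COLS + QUERY_INPUT_COLS + ("y",)

_VARIANTS = ("general", "spec_d", "spec_dl")


# ---------------------------------------------------------------------------
# metrics


def rmse(y, y_hat) -> float:
    """Root mean square error over panel cells."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    return float(np.sqrt(np.mean((y_hat - y) ** 2)))


def rer(y, y_hat) -> float:
    """Relative error rate: sum of absolute errors over sum of true values."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    denom = y.sum()
    if denom <= 0:
        raise ValueError("RER undefined: true incidences sum to zero")
    return float(np.abs(y_hat - y).sum() / denom)


# ---------------------------------------------------------------------------
# scaling


class IncidenceScaler(TransformerMixin, BaseEstimator):
    """Rescale incidences so the (training) maximum equals 1.

    Fit on training periods only; applied unchanged elsewhere.
    """

    def fit(self, y, sample_weight=None):
        y = np.asarray(y, dtype=float)
        m = y.max() if y.size else 0.0
        if m <= 0:
            raise ValueError("cannot rescale: maximum incidence is not positive")
        self.scale_ = 1.0 / m
        return self

    def transform(self, y):
        return np.asarray(y, dtype=float) * self.scale_


# ---------------------------------------------------------------------------
# panel aggregation


def _incidence_lookup(incidence, n_diseases, n_regions, n_periods) -> np.ndarray:
    if isinstance(incidence, pd.DataFrame):
        arr = np.zeros((n_diseases, n_regions, n_periods))
        for row in incidence.itertuples(index=False):
            arr[int(row.disease) - 1, int(row.region) - 1, int(row.period) - 1] = (
                row.incidence
            )
        return arr
    arr = np.asarray(incidence, dtype=float)
    if arr.shape != (n_diseases, n_regions, n_periods):
        raise ValueError(
            f"incidence array must have shape {(n_diseases, n_regions, n_periods)}"
        )
    return arr


def aggregate_panel(
    sessions: Sequence[Session],
    incidence,
    n_diseases: int = 15,
    n_regions: int = 4,
    n_periods: int = 16,
    records=None,
    query_set: QuerySet | None = None,
    lexicon: Lexicon | None = None,
    window: StudyWindow | None = None,
) -> pd.DataFrame:
    """Group intent-classified sessions into the estimation panel.

    ``x_sd(i, j, k)`` counts RD-intent sessions mentioning disease ``i`` in
    region ``j`` during season ``k`` (a session with several diseases
    increments each); ``x_sn`` does the same for news intent.  When
    ``records``/``query_set``/``lexicon``/``window`` are given, the query
    side (``x_name``/``x_gene``/``x_treat``) is aggregated from Query Set Q
    the same way.  ``y`` is the (unscaled) true incidence.
    """
    x_sd = np.zeros((n_diseases, n_regions, n_periods), dtype=int)
    x_sn = np.zeros_like(x_sd)
    for s in sessions:
        if s.intent == "UNLABELED":
            raise ValueError("every session must carry an intent")
        if not s.disease_ids:
            raise ValueError("session with empty disease_ids (not a valid member of S)")
        if s.period_id is None or s.region_id is None:
            raise ValueError("sessions must carry region_id and period_id")
        c = as_intent_index(s.intent)
        if c not in (RD, NEWS):
            continue
        target = x_sd if c == RD else x_sn
        for d in s.disease_ids:
            target[d - 1, s.region_id - 1, s.period_id - 1] += 1

    x_query = np.zeros((3, n_diseases, n_regions, n_periods), dtype=int)
    if records is not None:
        if query_set is None or lexicon is None or window is None:
            raise ValueError("query aggregation needs query_set, lexicon and window")
        cat_index = {c: m for m, c in enumerate(LEVEL1_CATEGORIES)}
        for rid in sorted(query_set.record_ids):
            rec = records[rid]
            ann = lexicon.match_query(rec.tokens)
            k = window.period_of(rec.timestamp)
            for d in ann.level1_hits:
                x_query[cat_index[ann.level1_category], d - 1, rec.region_id - 1, k - 1] += 1

    y = _incidence_lookup(incidence, n_diseases, n_regions, n_periods)
    d_idx, r_idx, k_idx = np.meshgrid(
        np.arange(n_diseases), np.arange(n_regions), np.arange(n_periods),
        indexing="ij",
    )
    return pd.DataFrame(
        {
            "disease": d_idx.ravel() + 1,
            "region": r_idx.ravel() + 1,
            "period": k_idx.ravel() + 1,
            "x_sd": x_sd.ravel(),
            "x_sn": x_sn.ravel(),
            "x_name": x_query[0].ravel(),
            "x_gene": x_query[1].ravel(),
            "x_treat": x_query[2].ravel(),
            "y": y.ravel(),
        }
    )


def split_by_year(
    panel: pd.DataFrame,
    train_periods: Sequence[int] = tuple(range(1, 9)),
    val_periods: Sequence[int] = tuple(range(9, 13)),
    test_periods: Sequence[int] = tuple(range(13, 17)),
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Chronological split: first two years train, third validation, fourth test."""
    parts = []
    for periods in (train_periods, val_periods, test_periods):
        part = panel[panel["period"].isin(periods)].reset_index(drop=True)
        if part.empty:
            raise ValueError(f"empty split for periods {tuple(periods)}")
        parts.append(part)
    return tuple(parts)


# ---------------------------------------------------------------------------
# the estimator


class IncidenceRegressor(RegressorMixin, BaseEstimator):
    """Linear incidence estimator with optional disease/region factorization.

    Parameters
    ----------
    variant : {"general", "spec_d", "spec_dl"}
        Coefficient sharing: one global set, per-disease sets, or the
        multiplicative per-disease x per-region factorization.
    input_type : {"session", "query"}
        Session-intent counts (x_sd, x_sn) or raw level-1 query counts by
        category (x_name, x_gene, x_treat).
    learning_rate, max_epochs, patience
        Full-batch Adam on MSE with early stopping on the validation split
        (training loss when no validation data is given); the best epoch's
        parameters are restored.
    init_scale, seed
        Slope coefficients start at small positive values around
        ``init_scale``; region factors start at 1 and offsets at 0, so the
        factorized variant begins exactly at its per-disease reduction.

    Fitted attributes (session input): ``alpha_d_``, ``alpha_n_``,
    ``beta_`` and, for ``spec_dl``, ``theta_d_``, ``theta_n_``, ``phi_``;
    query input gets ``alpha_name_``/``alpha_gene_``/``alpha_treat_`` and
    ``theta_name_``/... instead.  ``history_`` records per-epoch train and
    validation MSE (epoch 0 is the initial state).
    """

    def __init__(
        self,
        variant: str = "spec_dl",
        input_type: str = "session",
        n_diseases: int = 15,
        n_regions: int = 4,
        learning_rate: float = 0.02,
        max_epochs: int = 1000,
        patience: int = 50,
        init_scale: float = 0.01,
        seed: int = 0,
    ):
        self.variant = variant
        self.input_type = input_type
        self.n_diseases = n_diseases
        self.n_regions = n_regions
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.patience = patience
        self.init_scale = init_scale
        self.seed = seed

    # -- data marshalling --------------------------------------------------

    @property
    def _count_cols(self):
        if self.input_type == "session":
            return SESSION_INPUT_COLS
        if self.input_type == "query":
            return QUERY_INPUT_COLS
        raise ValueError(f"unknown input_type {self.input_type!r}")

    def _design(self, X):
        """(disease idx, region idx, counts (n, m)) from a panel frame or array."""
        if isinstance(X, pd.DataFrame):
            d = X["disease"].to_numpy(dtype=int) - 1
            r = X["region"].to_numpy(dtype=int) - 1
            counts = X[list(self._count_cols)].to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            if X.shape[1] != 2 + len(self._count_cols):
                raise ValueError(
                    f"expected columns (disease, region, {', '.join(self._count_cols)})"
                )
            d = X[:, 0].astype(int) - 1
            r = X[:, 1].astype(int) - 1
            counts = X[:, 2:]
        if d.min() < 0 or d.max() >= self.n_diseases:
            raise ValueError("disease ids outside 1..n_diseases")
        if r.min() < 0 or r.max() >= self.n_regions:
            raise ValueError("region ids outside 1..n_regions")
        return d, r, counts

    # -- prediction --------------------------------------------------------

    def _predict_params(self, params, d, r, counts):
        m = counts.shape[1]
        if self.variant == "general":
            return counts @ params["alpha"] + params["beta"]
        if self.variant == "spec_d":
            y = params["beta"][d].copy()
            for j in range(m):
                y += params["alpha"][j, d] * counts[:, j]
            return y
        y = params["beta"][d] * params["phi"][r]
        for j in range(m):
            y += params["alpha"][j, d] * params["theta"][j, r] * counts[:, j]
        return y

    def predict(self, X, clip_negative: bool = False) -> np.ndarray:
        d, r, counts = self._design(X)
        y = self._predict_params(self.params_, d, r, counts)
        return np.maximum(y, 0.0) if clip_negative else y

    # -- fitting -----------------------------------------------------------

    def _init_params(self, m, rng):
        D, R = self.n_diseases, self.n_regions
        scale = self.init_scale
        if self.variant == "general":
            return {
                "alpha": scale * rng.uniform(0.5, 1.5, size=m),
                "beta": np.zeros(()),
            }
        if self.variant == "spec_d":
            return {
                "alpha": scale * rng.uniform(0.5, 1.5, size=(m, D)),
                "beta": np.zeros(D),
            }
        if self.variant == "spec_dl":
            return {
                "alpha": scale * rng.uniform(0.5, 1.5, size=(m, D)),
                "theta": np.ones((m, R)),
                "beta": np.zeros(D),
                "phi": np.ones(R),
            }
        raise ValueError(f"unknown variant {self.variant!r}")

    def _grads(self, params, d, r, counts, err):
        n = len(err)
        m = counts.shape[1]
        D, R = self.n_diseases, self.n_regions
        g = {}
        if self.variant == "general":
            g["alpha"] = 2.0 / n * (counts * err[:, None]).sum(axis=0)
            g["beta"] = np.asarray(2.0 / n * err.sum())
        elif self.variant == "spec_d":
            g["alpha"] = np.stack(
                [
                    2.0 / n * np.bincount(d, weights=err * counts[:, j], minlength=D)
                    for j in range(m)
                ]
            )
            g["beta"] = 2.0 / n * np.bincount(d, weights=err, minlength=D)
        else:
            g["alpha"] = np.stack(
                [
                    2.0 / n * np.bincount(
                        d, weights=err * params["theta"][j, r] * counts[:, j],
                        minlength=D,
                    )
                    for j in range(m)
                ]
            )
            g["theta"] = np.stack(
                [
                    2.0 / n * np.bincount(
                        r, weights=err * params["alpha"][j, d] * counts[:, j],
                        minlength=R,
                    )
                    for j in range(m)
                ]
            )
            g["beta"] = 2.0 / n * np.bincount(
                d, weights=err * params["phi"][r], minlength=D
            )
            g["phi"] = 2.0 / n * np.bincount(
                r, weights=err * params["beta"][d], minlength=R
            )
        return g

    def fit(self, X, y, X_val=None, y_val=None):
        if self.variant not in _VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        d, r, counts = self._design(X)
        y = np.asarray(y, dtype=float)
        have_val = X_val is not None
        if have_val:
            dv, rv, counts_v = self._design(X_val)
            yv = np.asarray(y_val, dtype=float)

        rng = np.random.default_rng(self.seed)
        params = self._init_params(counts.shape[1], rng)
        opt = Adam(params, lr=self.learning_rate)

        def mse(p, dd, rr, cc, yy):
            e = self._predict_params(p, dd, rr, cc) - yy
            return float(np.mean(e**2))

        self.history_ = [
            {
                "epoch": 0,
                "train_mse": mse(params, d, r, counts, y),
                "val_mse": mse(params, dv, rv, counts_v, yv) if have_val else None,
            }
        ]
        monitored0 = (
            self.history_[0]["val_mse"] if have_val else self.history_[0]["train_mse"]
        )
        best = (monitored0, {k: v.copy() for k, v in params.items()}, 0)
        since_best = 0
        for epoch in range(1, self.max_epochs + 1):
            err = self._predict_params(params, d, r, counts) - y
            opt.step(self._grads(params, d, r, counts, err))
            train_mse = mse(params, d, r, counts, y)
            val_mse = mse(params, dv, rv, counts_v, yv) if have_val else None
            self.history_.append(
                {"epoch": epoch, "train_mse": train_mse, "val_mse": val_mse}
            )
            monitored = val_mse if have_val else train_mse
            if monitored < best[0] - 1e-12:
                best = (monitored, {k: v.copy() for k, v in params.items()}, epoch)
                since_best = 0
            else:
                since_best += 1
                if since_best >= self.patience:
                    break
        self.params_ = best[1]
        self.best_epoch_ = best[2]
        self.n_iter_ = len(self.history_) - 1
        self._publish_params()
        return self

    def _publish_params(self):
        names = ("d", "n") if self.input_type == "session" else ("name", "gene", "treat")
        p = self.params_
        for j, nm in enumerate(names):
            setattr(self, f"alpha_{nm}_", np.asarray(p["alpha"])[..., j]
                    if self.variant == "general" else p["alpha"][j])
            if self.variant == "spec_dl":
                setattr(self, f"theta_{nm}_", p["theta"][j])
        self.beta_ = p["beta"]
        if self.variant == "spec_dl":
            self.phi_ = p["phi"]

    def best_train_mse(self) -> float:
        """Lowest training MSE reached over the optimization trajectory."""
        return min(h["train_mse"] for h in self.history_)


# ---------------------------------------------------------------------------
# end-to-end fit with the chronological protocol


@dataclass
class FitResult:
    model: IncidenceRegressor
    scaler: IncidenceScaler
    metrics: dict  # split -> {"rmse": ..., "rer": ...}


def fit_variant(
    panel: pd.DataFrame,
    variant: str = "spec_dl",
    input_type: str = "session",
    seed: int = 0,
    n_diseases: int | None = None,
    n_regions: int | None = None,
    **kwargs,
) -> FitResult:
    """Fit one estimator variant under the by-year protocol.

    Rescales incidence so the training maximum is 1 (scaler fit on the
    training periods only), trains with early stopping on the validation
    year, and reports RMSE / RER per split on the rescaled scale.
    """
    n_diseases = n_diseases or int(panel["disease"].max())
    n_regions = n_regions or int(panel["region"].max())
    train, val, test = split_by_year(panel)
    scaler = IncidenceScaler().fit(train["y"].to_numpy())
    model = IncidenceRegressor(
        variant=variant,
        input_type=input_type,
        n_diseases=n_diseases,
        n_regions=n_regions,
        seed=seed,
        **kwargs,
    )
    y_tr = scaler.transform(train["y"].to_numpy())
    y_va = scaler.transform(val["y"].to_numpy())
    model.fit(train, y_tr, X_val=val, y_val=y_va)
    metrics = {}
    for name, part in (("train", train), ("val", val), ("test", test)):
        y_true = scaler.transform(part["y"].to_numpy())
        y_hat = model.predict(part)
        metrics[name] = {"rmse": rmse(y_true, y_hat), "rer": rer(y_true, y_hat)}
    return FitResult(model=model, scaler=scaler, metrics=metrics)


# ---------------------------------------------------------------------------
# analyses


def news_weight_products(model: IncidenceRegressor) -> tuple[np.ndarray, float]:
    """Per-(disease, region) products of the news-session weights,
    a_n(i) * t_n(j), and the fraction that are negative."""
    if model.variant != "spec_dl" or model.input_type != "session":
        raise ValueError("news weights require the session-input spec_dl variant")
    products = np.outer(model.alpha_n_, model.theta_n_)
    return products, float((products < 0).mean())


def _minmax(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    span = v.max() - v.min()
    if span == 0:
        return np.zeros_like(v)  # constant series normalize to all zeros
    return (v - v.min()) / span


def case_series(
    panel: pd.DataFrame,
    model: IncidenceRegressor,
    disease: int,
    region: int,
    periods: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Per-season series (x_sd, x_sn, y, y_hat) for one disease and region,
    each min-max normalized to [0, 1] for plotting."""
    cells = panel[(panel["disease"] == disease) & (panel["region"] == region)]
    if periods is not None:
        cells = cells[cells["period"].isin(periods)]
    if cells.empty:
        raise ValueError(f"no cells for disease {disease}, region {region}")
    cells = cells.sort_values("period").reset_index(drop=True)
    return pd.DataFrame(
        {
            "period": cells["period"],
            "x_sd": _minmax(cells["x_sd"].to_numpy()),
            "x_sn": _minmax(cells["x_sn"].to_numpy()),
            "y": _minmax(cells["y"].to_numpy()),
            "y_hat": _minmax(model.predict(cells)),
        }
    )
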