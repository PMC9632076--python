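"""Rejection ABC: model choice and parameter posteriors.

Given a reference table of simulated (model, parameters, summary vector)
rows and an observed summary vector, each statistic is centred and scaled
by the reference table's mean and SD (statistics with zero SD carry no
information for the Euclidean distance and are dropped, with a report),
rows are ranked by Euclidean distance to the observed vector, and the
nearest ceil(epsilon * n) rows are accepted.  The posterior probability of
each model is its frequency among accepted rows; accepted parameter draws
form the (rejection) parameter posteriors.

Leave-one-out cross-validation classifies held-out reference rows as
pseudo-observations and reports the model-by-model confusion matrix — the
standard quality control for ABC model choice.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class ReferenceTable:
    """Rows of (model id, flattened parameters, summary statistics).

    Backed by a DataFrame whose first column is ``model``, followed by the
    parameter columns then the statistic columns; ``provenance`` records
    the master seed and per-model simulation count.
    """

    df: pd.DataFrame
    param_cols: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if "model" not in self.df.columns:
            raise ValueError("reference table requires a 'model' column")
        if len(self.df) == 0:
            raise ValueError("reference table is empty")

    @property
    def stat_cols(self) -> list[str]:
        skip = {"model", *self.param_cols}
        return [c for c in self.df.columns if c not in skip]

    @property
    def models(self) -> list[str]:
        return list(dict.fromkeys(self.df["model"]))

    def stats_matrix(self) -> np.ndarray:
        return self.df[self.stat_cols].to_numpy(dtype=float)

    def to_csv(self, path: str | Path) -> None:
        p = Path(path)
        self.df.to_csv(p, index=False)
        meta = {"param_cols": self.param_cols, "provenance": self.provenance}
        p.with_suffix(p.suffix + ".meta.json").write_text(
            json.dumps(meta, indent=2)
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "ReferenceTable":
        p = Path(path)
        df = pd.read_csv(p)
        meta_path = p.with_suffix(p.suffix + ".meta.json")
        if meta_path.exists():
            meta = json.loads(meta_path.read_text())
            return cls(df, param_cols=meta["param_cols"],
                       provenance=meta.get("provenance", {}))
        param_cols = [c for c in df.columns
                      if c.endswith(("_onset_years_bp", "_severity"))]
        return cls(df, param_cols=param_cols)


@dataclass
class ScalingReport:
    """Centre/scale used for standardization, plus dropped columns."""

    names: list[str]
    center: np.ndarray
    scale: np.ndarray
    dropped: list[str]

    def unscale(self, x: np.ndarray) -> np.ndarray:
        return x * self.scale + self.center


@dataclass
class ABCResult:
    """Outcome of one rejection step.

    ``accepted_idx`` are positional row indices into the reference table,
    sorted by non-decreasing distance (ties broken by row index);
    ``model_posteriors`` are acceptance frequencies per model, summing
    to 1.
    """

    tolerance: float
    accepted_idx: np.ndarray
    distances: np.ndarray  # distance of each accepted row, same order
    model_posteriors: pd.Series
    accepted_params: pd.DataFrame
    scaling: ScalingReport
    n_rows: int

    @property
    def best_model(self) -> str:
        return str(self.model_posteriors.idxmax())

    def param_quantiles(
        self, model: str, q: tuple[float, ...] = (0.025, 0.5, 0.975)
    ) -> pd.DataFrame:
        """Posterior quantiles of the accepted parameter draws of a model."""
        sub = self.accepted_params[self.accepted_params["model"] == model]
        num = sub.drop(columns=["model"]).dropna(axis=1, how="all")
        if len(num) == 0:
            return pd.DataFrame(index=list(q))
        return num.quantile(list(q))

    def to_report_dict(self) -> dict:
        return {
            "tolerance": self.tolerance,
            "n_reference_rows": self.n_rows,
            "n_accepted": int(len(self.accepted_idx)),
            "model_posteriors": {
                str(k): float(v) for k, v in self.model_posteriors.items()
            },
            "best_model": self.best_model,
            "dropped_statistics": self.scaling.dropped,
        }


def standardize(
    table: ReferenceTable,
    observed: np.ndarray | pd.Series,
    method: str = "sd",
) -> tuple[np.ndarray, np.ndarray, ScalingReport]:
    """Centre and scale table and observed vector by the table's spread.

    ``method="sd"`` centres by mean and scales by SD; ``method="mad"``
    centres by median and scales by the median absolute deviation.
    Statistics whose scale is zero are dropped from both and listed in the
    report (they cannot contribute to a scaled distance).
    """
    names = table.stat_cols
    X = table.stats_matrix()
    obs = _coerce_observed(observed, names)
    if method == "sd":
        center = X.mean(axis=0)
        scale = X.std(axis=0, ddof=0)
    elif method == "mad":
        center = np.median(X, axis=0)
        scale = np.median(np.abs(X - center), axis=0)
    else:
        raise ValueError(f"unknown scaling method {method!r}")
    keep = scale > 0
    if not keep.any():
        raise ValueError("every statistic has zero SD in the reference table")
    dropped = [n for n, k in zip(names, keep) if not k]
    kept_names = [n for n, k in zip(names, keep) if k]
    Xs = (X[:, keep] - center[keep]) / scale[keep]
    obs_s = (obs[keep] - center[keep]) / scale[keep]
    report = ScalingReport(names=kept_names, center=center[keep],
                           scale=scale[keep], dropped=dropped)
    return Xs, obs_s, report


def _coerce_observed(
    observed: np.ndarray | pd.Series, names: list[str]
) -> np.ndarray:
    if isinstance(observed, pd.Series):
        missing = [n for n in names if n not in observed.index]
        if missing:
            raise ValueError(f"observed vector lacks statistics: {missing[:5]}")
        return observed[names].to_numpy(dtype=float)
    obs = np.asarray(observed, dtype=float).ravel()
    if obs.size != len(names):
        raise ValueError(
            f"observed vector length {obs.size} != table statistics {len(names)}"
        )
    return obs


def reject(
    table: ReferenceTable,
    observed: np.ndarray | pd.Series,
    tolerance: float = 0.05,
    scaling: str = "sd",
) -> ABCResult:
    """Rejection ABC: accept the ceil(tolerance * n) nearest rows.

    Distances are Euclidean over the standardized statistics; ties at the
    acceptance boundary are broken by (distance, row index), making the
    result deterministic.
    """
    if not 0 < tolerance <= 1:
        raise ValueError("tolerance must lie in (0, 1]")
    Xs, obs_s, report = standardize(table, observed, method=scaling)
    dist = np.sqrt(((Xs - obs_s) ** 2).sum(axis=1))
    n = len(dist)
    n_accept = math.ceil(tolerance * n)
    order = np.lexsort((np.arange(n), dist))
    accepted = order[:n_accept]
    models = table.df["model"].to_numpy()
    post = (
        pd.Series(models[accepted])
        .value_counts(normalize=True)
        .reindex(table.models, fill_value=0.0)
    )
    accepted_params = table.df.iloc[accepted][["model", *table.param_cols]]
    accepted_params = accepted_params.reset_index(drop=True)
    return ABCResult(
        tolerance=tolerance,
        accepted_idx=accepted,
        distances=dist[accepted],
        model_posteriors=post,
        accepted_params=accepted_params,
        scaling=report,
        n_rows=n,
    )


def cross_validate(
    table: ReferenceTable,
    n_pseudo: int,
    tolerance: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Leave-one-out cross-validation of ABC model choice.

    For each model, ``n_pseudo`` reference rows are drawn at random,
    removed one at a time, classified against the remaining table by
    highest posterior, and tallied.  Returns the confusion matrix (rows:
    true model, columns: chosen model); each row sums to ``n_pseudo``.
    """
    models = table.models
    counts_per = table.df["model"].value_counts()
    for m in models:
        if counts_per[m] < n_pseudo + 1:
            raise ValueError(
                f"model {m!r} has {counts_per[m]} rows; need > n_pseudo"
            )
    conf = pd.DataFrame(0, index=models, columns=models, dtype=int)
    names = table.stat_cols
    for m in models:
        rows_m = np.flatnonzero((table.df["model"] == m).to_numpy())
        chosen = rng.choice(rows_m, size=n_pseudo, replace=False)
        for i in chosen:
            obs = table.df.iloc[i][names].astype(float)
            rest = ReferenceTable(
                table.df.drop(index=table.df.index[i]).reset_index(drop=True),
                param_cols=table.param_cols,
                provenance=table.provenance,
            )
            res = reject(rest, obs, tolerance)
            conf.loc[m, res.best_model] += 1
    return conf
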