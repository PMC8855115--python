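"""Model selection by the small-sample-corrected Akaike criterion (AICc).

Each family member is calibrated globally on the same training set; the
score

    AICc = n * ln(RSS / n) + 2p + (2p^2 + 2p) / (n - p - 1)

balances fit against free-parameter count ``p``. Following the convention
that a "sample" is one confluence curve, ``n`` defaults to the number of
curves while RSS is summed over every time point of every curve; an
alternative ``n`` equal to the total observation count is available.
Akaike weights ``w_i = exp(-d_i/2) / sum_j exp(-d_j/2)`` with
``d_i = AICc_i - min(AICc)`` give each candidate's relative likelihood; the
weight ratio ``w_a / w_b = exp((AICc_b - AICc_a)/2)`` is the "a is X times
more likely than b" reading.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import FractionatedRadiationModel

__all__ = ["aicc", "akaike_weights", "select_model", "SelectionResult"]

logger = logging.getLogger(__name__)

_RSS_FLOOR = 1e-300  # guards ln(RSS) on numerically perfect fits


def aicc(n: int, rss: float, p: int) -> float:
    """Corrected Akaike score for a least-squares fit.

    ``n`` is the sample count, ``rss`` the residual sum of squares and
    ``p`` the number of free parameters; requires ``n > p + 1``.
    """
    if n <= p + 1:
        raise ValueError(f"AICc requires n > p + 1 (n={n}, p={p})")
    if rss < 0:
        raise ValueError("rss must be >= 0")
    rss = max(float(rss), _RSS_FLOOR)
    return n * math.log(rss / n) + 2 * p + (2 * p * p + 2 * p) / (n - p - 1)


def akaike_weights(scores, convention: str = "akaike") -> np.ndarray:
    """Normalized relative likelihoods from a list of AICc scores.

    The default ``'akaike'`` convention is ``w_i \\propto exp(-d_i/2)`` with
    ``d_i = AICc_i - min(AICc)``, so the best (lowest-AICc) model gets the
    largest weight. ``'relative-delta'`` is an alternative normalization
    occasionally seen in print, ``w_i \\propto exp((AICc_i - min)/min)``;
    note it *inverts* the ranking (the worst model gets the largest weight)
    and is provided for comparison only.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size < 2:
        raise ValueError("need at least two scores")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if convention == "akaike":
        delta = scores - scores.min()
        raw = np.exp(-delta / 2.0)
    elif convention == "relative-delta":
        raw = np.exp((scores - scores.min()) / scores.min())
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return raw / raw.sum()


@dataclass
class SelectionResult:
    """Per-model scores and the selected (lowest-AICc) family member."""

    table: pd.DataFrame  # columns: model_id, label, p, n, rss, aicc, weight, converged
    selected_id: int
    results: dict  # model_id -> CalibrationResult

    @property
    def selected(self):
        return self.results[self.selected_id]

    def weight_ratio(self, id_a: int, id_b: int) -> float:
        """How many times more likely model ``id_a`` is than ``id_b``."""
        tab = self.table.set_index("model_id")
        return float(
            math.exp((tab.loc[id_b, "aicc"] - tab.loc[id_a, "aicc"]) / 2.0)
        )

    def to_dict(self) -> dict:
        return {
            "selected_id": int(self.selected_id),
            "models": self.table.to_dict(orient="records"),
        }


def select_model(
    training_set,
    family,
    growth,
    kinetics,
    schedules=None,
    dt: float = 0.01,
    sample_count: str = "curves",
    **fit_options,
) -> SelectionResult:
    """Calibrate every family member and rank them by AICc.

    ``sample_count='curves'`` uses the number of curves as the AICc sample
    size (RSS still sums over all time points); ``'observations'`` uses the
    total point count. Ties in AICc resolve to the model with fewer free
    parameters. A member that fails to converge is scored with its best
    achieved RSS and flagged in the table.
    """
    training_set = list(training_set)
    if not training_set:
        raise ValueError("training set is empty")
    if sample_count not in ("curves", "observations"):
        raise ValueError("sample_count must be 'curves' or 'observations'")
    cache: dict = {}
    rows = []
    results = {}
    for spec in family:
        model = FractionatedRadiationModel(
            training_set, spec, growth, kinetics, schedules=schedules, dt=dt,
            workspace_cache=cache,
        )
        res = model.fit(**fit_options)
        n = len(training_set) if sample_count == "curves" else res.n_obs
        score = aicc(n, res.rss, spec.n_free)
        if not res.converged:
            logger.warning("%s did not converge; scoring best achieved RSS", spec.label)
        rows.append(
            {
                "model_id": spec.id,
                "label": spec.label,
                "p": spec.n_free,
                "n": n,
                "rss": res.rss,
                "aicc": score,
                "converged": bool(res.converged),
            }
        )
        results[spec.id] = res
    table = pd.DataFrame(rows)
    table["weight"] = akaike_weights(table["aicc"].to_numpy())
    # argmin AICc; ties go to the smaller model
    order = table.sort_values(["aicc", "p"], kind="stable")
    selected_id = int(order.iloc[0]["model_id"])
    return SelectionResult(table=table, selected_id=selected_id, results=results)
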