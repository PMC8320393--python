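"""Constrained in-silico formulation search.

Candidate media are drawn uniformly over the continuous coded space
[−1, +1] per component, with per-component constraints (fix a level, or
bound it from above/below).  Every final donor model scores the shared
candidate set and its top-N formulations are pooled with full provenance
(donor, response, model, predicted value, rank).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import FittedModel

__all__ = [
    "Constraint",
    "parse_constraint",
    "sample_formulations",
    "predict_batch",
    "top_n_pool",
    "pool_factor_columns",
]

POOL_META = ("donor_id", "response", "model_id", "predicted", "rank")


@dataclass(frozen=True)
class Constraint:
    """Restriction of one component in coded units."""

    factor_id: str
    kind: str  # fix | upper_bound | lower_bound
    value: float

    def __post_init__(self) -> None:
        if self.kind not in ("fix", "upper_bound", "lower_bound"):
            raise ValueError(f"unknown constraint kind {self.kind!r}")
        if not -1.0 <= self.value <= 1.0:
            raise ValueError("constraint value must lie in coded [-1, 1]")

    def satisfied(self, column: np.ndarray, atol: float = 1e-12) -> np.ndarray:
        if self.kind == "fix":
            return np.abs(column - self.value) <= atol
        if self.kind == "upper_bound":
            return column <= self.value + atol
        return column >= self.value - atol


def parse_constraint(text: str) -> Constraint:
    """Parse CLI shorthand: ``c02=0``, ``c05<=0.5``, ``c01>=-1``."""
    for op, kind in (("<=", "upper_bound"), (">=", "lower_bound"), ("=", "fix")):
        if op in text:
            fid, val = text.split(op, 1)
            return Constraint(fid.strip(), kind, float(val))
    raise ValueError(f"cannot parse constraint {text!r}")


def sample_formulations(
    n: int,
    factor_ids: list[str],
    constraints: list[Constraint] | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw ``n`` random formulations over the coded experimental space.

    Free components are independent Uniform(−1, 1); fixed components are
    set exactly; bounded components are drawn uniformly over the allowed
    sub-interval.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    constraints = constraints or []
    by_factor: dict[str, list[Constraint]] = {}
    for c in constraints:
        if c.factor_id not in factor_ids:
            raise ValueError(f"constraint on unknown factor {c.factor_id!r}")
        by_factor.setdefault(c.factor_id, []).append(c)
    rng = np.random.default_rng(seed)
    X = np.empty((n, len(factor_ids)))
    for j, fid in enumerate(factor_ids):
        lo, hi = -1.0, 1.0
        fixed = None
        for c in by_factor.get(fid, []):
            if c.kind == "fix":
                if fixed is not None and fixed != c.value:
                    raise ValueError(f"conflicting fix constraints on {fid}")
                fixed = c.value
            elif c.kind == "upper_bound":
                hi = min(hi, c.value)
            else:
                lo = max(lo, c.value)
        if fixed is not None:
            if not lo <= fixed <= hi:
                raise ValueError(f"conflicting constraints on {fid}")
            X[:, j] = fixed
        else:
            if lo > hi:
                raise ValueError(f"conflicting bound constraints on {fid}")
            X[:, j] = rng.uniform(lo, hi, n)
    return pd.DataFrame(X, columns=factor_ids)


def predict_batch(model: FittedModel, formulations: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Score formulations with one fitted model (scaling handled inside)."""
    X = (
        formulations.to_numpy(dtype=float)
        if isinstance(formulations, pd.DataFrame)
        else np.asarray(formulations, dtype=float)
    )
    return model.predict(X)


def top_n_pool(
    finals: dict[tuple[str, str], FittedModel],
    formulations: pd.DataFrame,
    n_top: int = 40,
) -> pd.DataFrame:
    """Pool each final model's top-N formulations (both responses maximized).

    Ties in predicted value are broken by formulation row index, so the
    pool is deterministic.  Duplicate formulations selected by several
    models are retained — overlap is informative for the clustering step.
    """
    if n_top > len(formulations):
        raise ValueError("n_top exceeds the number of candidate formulations")
    pieces = []
    for (donor, response), model in sorted(finals.items()):
        pred = predict_batch(model, formulations)
        order = np.lexsort((np.arange(len(pred)), -pred))[:n_top]
        top = formulations.iloc[order].reset_index(drop=True).copy()
        top["donor_id"] = donor
        top["response"] = response
        top["model_id"] = model.model_id
        top["predicted"] = pred[order]
        top["rank"] = np.arange(1, n_top + 1)
        pieces.append(top)
    return pd.concat(pieces, ignore_index=True)


def pool_factor_columns(pool: pd.DataFrame) -> list[str]:
    return [c for c in pool.columns if c not in POOL_META]
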