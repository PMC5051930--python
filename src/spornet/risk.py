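"""Risk adjustment of binary encounter outcomes.

A raw binary outcome y ignores how likely a positive outcome was at
baseline: it penalises providers for bad outcomes in encounters that were
always unlikely to go well, and rewards them for easy wins.  The remedy is
a two-step risk adjustment:

1. fit a logistic regression of the outcome on baseline covariates
   (typically triage acuity), giving each encounter a fitted positive-
   outcome probability p = Pr(y = 1 | x);
2. map (y, p) onto the risk-adjusted outcome

       r = (1 + y - p) / 2  ∈  [0, 1].

r rewards unexpectedly good outcomes (y=1 with small p gives r near 1),
heavily penalises unexpectedly bad ones (y=0 with large p gives r near 0),
and leaves expected outcomes near the middle: y=1 with p near 1 gives
r ≈ 0.5, y=0 with p near 0 gives r ≈ 0.5.  For any fixed p, the reward for
a positive over a negative outcome is exactly 1/2.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .types import EncounterRecord

#: fitted probabilities are clipped into [CLIP, 1-CLIP] before computing r,
#: guarding downstream sums against degenerate 0/1 fits
CLIP = 1e-9

_INTERCEPT = "const"


@dataclass(frozen=True)
class CovariateSpec:
    """Declaration of one baseline covariate.

    ``kind`` is ``"categorical"`` (dummy-expanded against a reference
    level — by default the most frequent level) or ``"numeric"``.  Ordinal
    covariates such as acuity default to categorical but may be declared
    numeric when a linear log-odds trend is wanted.
    """

    name: str
    kind: str = "categorical"
    reference: object | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("categorical", "numeric"):
            raise ValueError(f"kind must be categorical|numeric, got {self.kind!r}")


@dataclass(frozen=True)
class RiskAdjustedOutcome:
    """Per-encounter fitted probability p and risk-adjusted outcome r."""

    encounter_id: str
    p: float
    r: float


@dataclass
class RiskModel:
    """A fitted logistic outcome model.

    ``coefficients`` maps design-column names (``const``, numeric covariate
    names, and ``name=level`` dummies) to maximum-likelihood estimates.
    ``levels`` records the observed levels and the reference level of each
    categorical covariate so that prediction on new encounters expands the
    design identically.
    """

    coefficients: dict[str, float]
    spec: tuple[CovariateSpec, ...]
    levels: dict[str, dict] = field(default_factory=dict)
    converged: bool = True
    log_likelihood: float = float("nan")
    standard_errors: dict[str, float] = field(default_factory=dict)

    # -- prediction ---------------------------------------------------

    def _design_row(self, covariates: Mapping[str, object]) -> dict[str, float]:
        row = {_INTERCEPT: 1.0}
        for cov in self.spec:
            value = covariates.get(cov.name)
            if value is None:
                raise ValueError(f"missing covariate {cov.name!r}")
            if cov.kind == "numeric":
                row[cov.name] = float(value)  # type: ignore[arg-type]
            else:
                info = self.levels[cov.name]
                if value not in info["levels"]:
                    raise ValueError(
                        f"unseen level {value!r} for covariate {cov.name!r}"
                    )
                for lev in info["levels"]:
                    if lev != info["reference"]:
                        row[f"{cov.name}={lev}"] = float(value == lev)
        return row

    def predict_proba(self, covariates: Mapping[str, object]) -> float:
        """Fitted positive-outcome probability for one covariate vector."""
        row = self._design_row(covariates)
        eta = sum(self.coefficients[k] * v for k, v in row.items())
        return float(1.0 / (1.0 + np.exp(-eta)))

    # -- persistence --------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        doc = {
            "coefficients": self.coefficients,
            "spec": [
                {"name": c.name, "kind": c.kind, "reference": c.reference}
                for c in self.spec
            ],
            "levels": {
                k: {"levels": list(v["levels"]), "reference": v["reference"]}
                for k, v in self.levels.items()
            },
            "converged": self.converged,
            "log_likelihood": self.log_likelihood,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RiskModel":
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
        return cls(
            coefficients=dict(doc["coefficients"]),
            spec=tuple(CovariateSpec(**c) for c in doc["spec"]),
            levels={
                k: {"levels": list(v["levels"]), "reference": v["reference"]}
                for k, v in doc["levels"].items()
            },
            converged=doc.get("converged", True),
            log_likelihood=doc.get("log_likelihood", float("nan")),
        )


def _complete_cases(
    encounters: Iterable[EncounterRecord], spec: Sequence[CovariateSpec]
) -> list[EncounterRecord]:
    kept = []
    for enc in encounters:
        if enc.outcome is None:
            continue
        if any(enc.covariates.get(c.name) is None for c in spec):
            continue
        kept.append(enc)
    return kept


def fit_risk_model(
    encounters: Iterable[EncounterRecord],
    covariate_spec: Sequence[CovariateSpec] = (),
) -> RiskModel:
    """Fit the logistic outcome model by maximum likelihood.

    Only encounters with an observed outcome and complete covariates enter
    the fit (complete-case analysis).  With an empty ``covariate_spec`` an
    intercept-only model is fitted, whose fitted probability is exactly the
    observed positive rate.

    Raises
    ------
    ValueError
        If outcomes are all-positive or all-negative, a categorical
        covariate has a single observed level, or the likelihood fails to
        converge / separates perfectly (named by design column).
    """
    spec = tuple(covariate_spec)
    rows = _complete_cases(encounters, spec)
    if len(rows) < 2:
        raise ValueError("need at least two complete-case encounters to fit")
    y = np.array([e.outcome for e in rows], dtype=float)
    if y.min() == y.max():
        raise ValueError("outcomes are all identical; logistic fit undefined")

    cols: dict[str, np.ndarray] = {_INTERCEPT: np.ones(len(rows))}
    levels: dict[str, dict] = {}
    for cov in spec:
        values = [e.covariates[cov.name] for e in rows]
        if cov.kind == "numeric":
            cols[cov.name] = np.asarray(values, dtype=float)
        else:
            series = pd.Series(values)
            observed = sorted(
                (v.item() if hasattr(v, "item") else v for v in series.unique()),
                key=str,
            )
            if len(observed) < 2:
                raise ValueError(
                    f"categorical covariate {cov.name!r} has a single level"
                )
            if cov.reference is not None:
                if cov.reference not in observed:
                    raise ValueError(
                        f"reference {cov.reference!r} not observed for {cov.name!r}"
                    )
                ref = cov.reference
            else:
                ref = series.value_counts().idxmax()
                ref = ref.item() if hasattr(ref, "item") else ref
            levels[cov.name] = {"levels": observed, "reference": ref}
            for lev in observed:
                if lev != ref:
                    cols[f"{cov.name}={lev}"] = (series == lev).to_numpy(float)

    X = pd.DataFrame(cols)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            result = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except Exception as exc:  # statsmodels raises on hard separation
            raise ValueError(f"logistic fit failed on design {list(X.columns)}: {exc}")
    params = dict(zip(X.columns, map(float, result.params)))
    converged = bool(result.mle_retvals.get("converged", False))
    runaway = [k for k, v in params.items() if abs(v) > 30]
    if not converged or runaway:
        raise ValueError(
            "logistic fit did not converge (possible perfect separation); "
            f"suspect design column(s): {runaway or list(X.columns)}"
        )
    return RiskModel(
        coefficients=params,
        spec=spec,
        levels=levels,
        converged=converged,
        log_likelihood=float(result.llf),
        standard_errors=dict(zip(X.columns, map(float, result.bse))),
    )


def risk_adjust(y: int, p: float) -> float:
    """Risk-adjusted outcome r = (1 + y - p) / 2.

    ``y`` must be 0 or 1 and ``p`` must lie in [0, 1] (boundary values are
    accepted; callers that want them flagged should clip first).
    """
    if y not in (0, 1):
        raise ValueError(f"y must be 0 or 1, got {y!r}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must lie in [0, 1], got {p!r}")
    return (1.0 + y - p) / 2.0


def risk_adjusted_outcomes(
    encounters: Iterable[EncounterRecord],
    model: RiskModel,
    clip: float = CLIP,
) -> dict[str, RiskAdjustedOutcome]:
    """Compute r for every encounter with an outcome and complete covariates.

    Fitted probabilities are clipped into ``[clip, 1 - clip]`` so r never
    reaches the degenerate values a 0/1 fitted probability would produce.
    """
    out: dict[str, RiskAdjustedOutcome] = {}
    for enc in _complete_cases(encounters, model.spec):
        p = min(max(model.predict_proba(enc.covariates), clip), 1.0 - clip)
        out[enc.encounter_id] = RiskAdjustedOutcome(
            enc.encounter_id, p=p, r=risk_adjust(enc.outcome, p)
        )
    return out
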