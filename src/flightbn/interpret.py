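"""Sensitivity analysis and influence runs on a fitted network.

Sensitivity rows report, per predictor F, the mutual information with the
class under the model joint,  MI(C; F) = sum P(c, f) log2[P(c, f)/(P(c)
P(f))]  in bits; Percent = 100 MI / H(C) with the class entropy also in
bits; and the variance of beliefs  VB = sum_f P(f) [P(c*|f) - P(c*)]^2
for the target state c* = flight true.  Rows sort by VB descending.

Influence runs sweep each state of a single predictor as sole evidence and
record the flight posterior against the no-evidence ("normative")
baseline; the tornado summary sorts predictors by posterior range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bayesnet import BNModel, posterior_flight


def _feature_class_joint(model: BNModel, feature: str) -> np.ndarray:
    """P(c, f) under the model, shape (n_class, n_feature_states).

    Computed top-down along the feature tree: P(x | c) for a root feature
    is its CPT row; for a child, sum_parent P(parent | c) P(x | parent, c).
    """
    s = model.structure
    # P(x_v | c) for every feature, memoized walk up the tree
    cond: dict[str, np.ndarray] = {}

    def p_given_c(f: str) -> np.ndarray:
        if f in cond:
            return cond[f]
        parent = s.feature_parent(f)
        nc = s.n_states[s.class_var]
        if parent is None:
            out = model.cpts[f]  # (nc, nf)
        else:
            pp = p_given_c(parent)  # (nc, np_states)
            out = np.einsum("cp,cpf->cf", pp, model.cpts[f])
        cond[f] = out
        return out

    p_c = model.cpts[s.class_var]
    return p_c[:, None] * p_given_c(feature)


def class_entropy_bits(p_c: np.ndarray) -> float:
    p = np.asarray(p_c, dtype=float)
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def mutual_information_bits(joint: np.ndarray) -> float:
    p_c = joint.sum(axis=1)
    p_f = joint.sum(axis=0)
    mi = 0.0
    for c in range(joint.shape[0]):
        for f in range(joint.shape[1]):
            pcf = joint[c, f]
            if pcf <= 0:
                continue
            mi += pcf * np.log2(pcf / (p_c[c] * p_f[f]))
    return float(max(mi, 0.0))


def sensitivity_table(model: BNModel, target_state: int = 1) -> pd.DataFrame:
    """Mutual information, Percent and variance of beliefs per predictor."""
    s = model.structure
    p_c = model.cpts[s.class_var]
    h_c = class_entropy_bits(p_c)
    rows = []
    for f in s.features:
        joint = _feature_class_joint(model, f)
        p_f = joint.sum(axis=0)
        # law of total probability must hold under the model joint
        assert np.allclose(joint.sum(axis=1), p_c, atol=1e-9)
        mi = mutual_information_bits(joint)
        with np.errstate(divide="ignore", invalid="ignore"):
            p_c_given_f = np.where(p_f > 0, joint[target_state] / p_f, 0.0)
        vb = float(np.sum(p_f * (p_c_given_f - p_c[target_state]) ** 2))
        rows.append(
            {
                "variable": f,
                "mutual_information": mi,
                "percent": 100.0 * mi / h_c if h_c > 0 else 0.0,
                "variance_of_beliefs": vb,
            }
        )
    out = pd.DataFrame(rows).sort_values(
        ["variance_of_beliefs", "variable"], ascending=[False, True]
    )
    return out.reset_index(drop=True)


@dataclass
class InfluenceResult:
    variable: str
    per_state: np.ndarray  # P(flight=true) per state of the variable
    baseline: float  # no-evidence posterior

    @property
    def min(self) -> float:
        return float(self.per_state.min())

    @property
    def max(self) -> float:
        return float(self.per_state.max())

    @property
    def range(self) -> float:
        return self.max - self.min

    @property
    def grey_span(self) -> float:
        """Potential reduction in flight probability below the baseline."""
        return self.baseline - self.min

    @property
    def black_span(self) -> float:
        """Potential increase in flight probability above the baseline."""
        return self.max - self.baseline


def influence_run(model: BNModel, variable: str, target_state: int = 1) -> InfluenceResult:
    """Sweep each state of ``variable`` as sole evidence; all other
    predictors stay at their priors."""
    s = model.structure
    if variable not in s.features:
        raise KeyError(f"unknown variable {variable!r}")
    baseline = float(posterior_flight(model, {})[target_state])
    per_state = np.array(
        [
            posterior_flight(model, {variable: st})[target_state]
            for st in range(s.n_states[variable])
        ]
    )
    return InfluenceResult(variable, per_state, baseline)


def tornado(model: BNModel, target_state: int = 1) -> list[InfluenceResult]:
    """Influence runs for every predictor, sorted by range descending
    (ties broken by variable name)."""
    results = [influence_run(model, f, target_state) for f in model.structure.features]
    return sorted(results, key=lambda r: (-r.range, r.variable))


def tornado_frame(results: list[InfluenceResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "variable": r.variable,
                "baseline": r.baseline,
                "min": r.min,
                "max": r.max,
                "range": r.range,
                "grey_span": r.grey_span,
                "black_span": r.black_span,
            }
            for r in results
        ]
    )
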