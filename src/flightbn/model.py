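"""Model/Results facade over the flight-activity pipeline.

``FlightActivityModel`` is constructed from a case file and a species and
``fit()`` runs supervised discretization, structure learning (TAN by
default; naive Bayes, or automatic selection by training classification
accuracy) and EM parameterization.  The returned
``FlightActivityResults`` carries the fitted network, scored cases,
calibration metrics, threshold errors, sensitivity and influence
summaries, and a text ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bayesnet import BNModel, BNStructure, fit_cpts_em, learn_tan_structure, model_summary, score_cases
from .data_model import COVARIATES, CaseFile
from .discretize import apply_schemes, mdl_supervised_cuts
from .evaluate import (
    GRID,
    THRESHOLDS_REPORTED,
    ScoredCases,
    calibration_metrics,
    confusion_at_threshold,
    repeated_kfold_cv,
    type2_roc,
)
from .interpret import sensitivity_table, tornado, tornado_frame

CLASS_VAR = "flight"


def _discretize_features(cf: CaseFile, species: str, subset=None, covariates=None):
    covariates = tuple(covariates) if covariates is not None else COVARIATES
    df = cf.data if subset is None else cf.data[subset]
    y = cf.flight_flags(species)
    y = y if subset is None else y[subset]
    schemes = {}
    for var in covariates:
        scheme = mdl_supervised_cuts(df[var].to_numpy(dtype=float), y.to_numpy(), variable=var)
        if scheme.informative:
            schemes[var] = scheme
    return schemes, y


def _discrete_table(cf: CaseFile, species: str, schemes: dict, subset=None):
    df = cf.data if subset is None else cf.data[subset]
    disc = apply_schemes(df, list(schemes.values()))
    y = cf.flight_flags(species)
    y = y if subset is None else y[subset]
    disc[CLASS_VAR] = y.astype(int).to_numpy()
    return disc


def learn_flight_bn(
    cf: CaseFile,
    species: str,
    subset=None,
    covariates=None,
    alpha: float = 1.0,
    structure: str = "tan",
    em_tol: float = 1e-6,
    em_max_iter: int = 200,
) -> BNModel:
    """Full learning pass on (a subset of) a case file.

    When every supervised discretization is uninformative the classifier
    degrades to the class prior alone (no features).
    """
    schemes, _ = _discretize_features(cf, species, subset, covariates)
    disc = _discrete_table(cf, species, schemes, subset)
    n_states = {v: s.n_states for v, s in schemes.items()}
    n_states[CLASS_VAR] = 2
    features = tuple(schemes.keys())
    if len(features) == 0:
        y = disc[CLASS_VAR].to_numpy()
        prior = np.array([np.mean(y == 0), np.mean(y == 1)])
        struct = BNStructure(CLASS_VAR, (), {CLASS_VAR: 2}, ())
        return BNModel(struct, {CLASS_VAR: prior}, {})
    if structure == "tan" and len(features) >= 2:
        struct = learn_tan_structure(disc, CLASS_VAR, n_states, alpha=alpha)
    elif structure in ("naive", "tan"):
        struct = BNStructure(CLASS_VAR, features, n_states, ())
    elif structure == "auto":
        return _select_structure(cf, species, subset, covariates, alpha, em_tol, em_max_iter)
    else:
        raise ValueError(f"unknown structure {structure!r}")
    cpts = fit_cpts_em(struct, disc, alpha=alpha, tol=em_tol, max_iter=em_max_iter)
    return BNModel(struct, cpts, schemes)


def _select_structure(cf, species, subset, covariates, alpha, em_tol, em_max_iter):
    """Pick naive vs TAN by training classification accuracy at tau = 0.5."""
    best = None
    for structure in ("naive", "tan"):
        model = learn_flight_bn(
            cf, species, subset, covariates, alpha, structure, em_tol, em_max_iter
        )
        p = score_casefile(model, cf, subset)
        y = cf.flight_flags(species)
        y = (y if subset is None else y[subset]).to_numpy()
        acc = float(np.mean((p >= 0.5) == y))
        if best is None or acc > best[0]:
            best = (acc, model)
    return best[1]


def score_casefile(model: BNModel, cf: CaseFile, subset=None) -> np.ndarray:
    """P(flight = true) per case under the fitted network."""
    df = cf.data if subset is None else cf.data[subset]
    if not model.structure.features:
        return np.full(len(df), float(model.cpts[CLASS_VAR][1]))
    disc = apply_schemes(df, list(model.schemes.values()))
    return score_cases(model, disc)


class FlightActivityModel:
    """Hourly flight-activity classifier for one species.

    Parameters
    ----------
    casefile : CaseFile
        Validated hourly cases (fault days should already be excluded and
        anomalies flagged).
    species : str
        One of the case file's species names.
    covariates : sequence of str, optional
        Continuous covariates offered to the supervised discretizer;
        defaults to all nine temporal/abiotic variables.
    structure : {"tan", "naive", "auto"}
        Network structure; "auto" compares training classification
        accuracy at threshold 0.5.
    alpha : float
        Dirichlet pseudo-count for CMI smoothing and EM.
    """

    def __init__(
        self,
        casefile: CaseFile,
        species: str,
        covariates=None,
        structure: str = "tan",
        alpha: float = 1.0,
    ) -> None:
        if species not in casefile.species:
            raise KeyError(f"unknown species {species!r}")
        self.casefile = casefile
        self.species = species
        self.covariates = tuple(covariates) if covariates is not None else COVARIATES
        self.structure = structure
        self.alpha = alpha

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, species: str, **kwargs) -> "FlightActivityModel":
        return cls(CaseFile(data), species, **kwargs)

    def fit(self, em_tol: float = 1e-6, em_max_iter: int = 200) -> "FlightActivityResults":
        bn = learn_flight_bn(
            self.casefile,
            self.species,
            covariates=self.covariates,
            alpha=self.alpha,
            structure=self.structure,
            em_tol=em_tol,
            em_max_iter=em_max_iter,
        )
        p = score_casefile(bn, self.casefile)
        truth = self.casefile.flight_flags(self.species).to_numpy()
        return FlightActivityResults(self, bn, ScoredCases(p, truth))


@dataclass
class FlightActivityResults:
    """Fitted network plus calibration diagnostics for one species."""

    model: FlightActivityModel
    bn: BNModel
    scored: ScoredCases
    _metrics: dict = field(default=None, repr=False)

    @property
    def metrics(self) -> dict:
        if self._metrics is None:
            self._metrics = calibration_metrics(self.scored)
        return self._metrics

    def threshold_errors(self, thresholds=THRESHOLDS_REPORTED) -> pd.DataFrame:
        rows = [
            {"threshold": tau, **confusion_at_threshold(self.scored, tau)}
            for tau in thresholds
        ]
        return pd.DataFrame(rows)

    def type2_roc(self, grid=GRID) -> pd.DataFrame:
        return type2_roc(self.scored, grid)

    def sensitivity(self) -> pd.DataFrame:
        return sensitivity_table(self.bn)

    def tornado(self) -> pd.DataFrame:
        return tornado_frame(tornado(self.bn))

    def network_summary(self) -> dict:
        return model_summary(self.bn)

    def crossval(self, k: int = 4, iterations: int = 100, seed: int = 0, **kwargs):
        return repeated_kfold_cv(
            self.model.casefile,
            self.model.species,
            k=k,
            iterations=iterations,
            seed=seed,
            covariates=self.model.covariates,
            alpha=self.model.alpha,
            **kwargs,
        )

    def summary(self) -> str:
        ms = self.network_summary()
        lines = [
            f"Flight-activity Bayesian network: {self.model.species}",
            "=" * 54,
            f"Cases: {len(self.model.casefile)}   positive hours: {int(self.scored.truth.sum())}"
            f" ({100.0 * self.scored.truth.mean():.1f}%)",
            f"Structure: {len(self.bn.structure.features)} predictors, "
            f"{len(self.bn.structure.tree_edges)} tree edges "
            f"({ms['n_nodes']} nodes, {ms['n_linkages']} linkages, "
            f"{ms['n_probabilities']} probabilities)",
            "",
            "Calibration scores",
            "-" * 54,
        ]
        for k_, v in self.metrics.items():
            lines.append(f"  {k_:<20s} {v:8.3f}")
        lines += ["", "Errors by no-flight threshold (%)", "-" * 54,
                  f"  {'tau':>5s} {'Type I':>8s} {'Type II':>8s} {'Total':>8s}"]
        for _, r in self.threshold_errors().iterrows():
            lines.append(
                f"  {r['threshold']:>5.2f} {r['type1_pct']:>8.1f} "
                f"{r['type2_pct']:>8.1f} {r['total_pct']:>8.1f}"
            )
        sens = self.sensitivity()
        lines += ["", "Sensitivity (variance of beliefs, descending)", "-" * 54]
        for _, r in sens.iterrows():
            lines.append(
                f"  {r['variable']:<16s} MI={r['mutual_information']:.5f} bits  "
                f"{r['percent']:5.1f}%  VB={r['variance_of_beliefs']:.6f}"
            )
        return "\n".join(lines)
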