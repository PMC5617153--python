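"""Tree-augmented naive Bayes: structure learning, EM parameters, inference.

Structure.  Every feature is a child of the binary class node (flight
true/false).  TAN additionally connects the features by a tree: the
maximum-weight spanning tree under conditional mutual information
I(Xi; Xj | C), directed outward from a deterministic root (the first
feature in canonical variable order), so each feature has at most one
feature parent.

Parameters.  Conditional probability tables are learnt by EM with a
Dirichlet pseudo-count alpha (default 1).  On complete data a single
iteration reproduces the Laplace-smoothed closed form
(count + alpha)/(total + alpha * n_states); with missing covariates the
E-step adds expected counts under the current posteriors, and the
observed-data log-likelihood never decreases.

Inference.  Exact, by message passing over the feature tree conditioned on
each class value; linear in the number of features, so full-casefile
scoring is cheap.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .discretize import DiscretizationScheme


@dataclass
class BNStructure:
    """Class node plus feature nodes, each with <= 1 feature parent."""

    class_var: str
    features: tuple[str, ...]
    n_states: dict
    tree_edges: tuple[tuple[str, str], ...]  # (parent, child), both features
    notice: str | None = None

    def __post_init__(self) -> None:
        self.features = tuple(self.features)
        self.tree_edges = tuple((p, c) for p, c in self.tree_edges)
        parents: dict[str, str] = {}
        for p, c in self.tree_edges:
            if c in parents:
                raise ValueError(f"feature {c!r} has two feature parents")
            parents[c] = p
        # acyclicity: walking up from any node must terminate
        for f in self.features:
            seen = set()
            cur = f
            while cur in parents:
                if cur in seen:
                    raise ValueError("feature-parent graph has a cycle")
                seen.add(cur)
                cur = parents[cur]

    def feature_parent(self, feature: str) -> str | None:
        for p, c in self.tree_edges:
            if c == feature:
                return p
        return None

    @property
    def children(self) -> dict:
        ch: dict[str, list[str]] = {f: [] for f in self.features}
        for p, c in self.tree_edges:
            ch[p].append(c)
        return ch

    @property
    def roots(self) -> list[str]:
        withparent = {c for _, c in self.tree_edges}
        return [f for f in self.features if f not in withparent]


def _cmi(table: np.ndarray) -> float:
    """Conditional mutual information I(X; Y | C) in nats from a joint count
    table of shape (nx, ny, nc), already smoothed."""
    p = table / table.sum()
    p_c = p.sum(axis=(0, 1))
    p_xc = p.sum(axis=1)
    p_yc = p.sum(axis=0)
    mi = 0.0
    nx, ny, nc = p.shape
    for c in range(nc):
        for i in range(nx):
            for j in range(ny):
                pij = p[i, j, c]
                if pij <= 0:
                    continue
                mi += pij * np.log(pij * p_c[c] / (p_xc[i, c] * p_yc[j, c]))
    return float(mi)


def conditional_mutual_information(
    data: pd.DataFrame, xi: str, xj: str, class_var: str, n_states: dict, alpha: float = 1.0
) -> float:
    """Smoothed empirical I(Xi; Xj | C); missing-covariate rows are dropped
    pairwise."""
    sub = data[[xi, xj, class_var]].dropna()
    table = np.full((n_states[xi], n_states[xj], n_states[class_var]), alpha, dtype=float)
    xi_v = sub[xi].to_numpy(dtype=int)
    xj_v = sub[xj].to_numpy(dtype=int)
    c_v = sub[class_var].to_numpy(dtype=int)
    np.add.at(table, (xi_v, xj_v, c_v), 1.0)
    return _cmi(table)


def learn_tan_structure(
    data: pd.DataFrame, class_var: str, n_states: dict, alpha: float = 1.0
) -> BNStructure:
    """Maximum-weight spanning tree over features under CMI given the class.

    Deterministic: ties in weight are broken by lexicographic edge name;
    edges are directed outward from the first feature in canonical
    (column) order.  A single feature degrades to naive Bayes with a
    notice.
    """
    features = tuple(c for c in data.columns if c != class_var)
    if len(features) < 1:
        raise ValueError("need at least one feature")
    if len(features) == 1:
        return BNStructure(class_var, features, dict(n_states), (), notice="single feature: naive Bayes")
    weights = {}
    for a, b in itertools.combinations(features, 2):
        weights[(a, b)] = conditional_mutual_information(data, a, b, class_var, n_states, alpha)
    # Kruskal with deterministic ordering: by descending weight, then name
    edges = sorted(weights.items(), key=lambda kv: (-kv[1], kv[0]))
    parent_of = {f: f for f in features}

    def find(x):
        while parent_of[x] != x:
            parent_of[x] = parent_of[parent_of[x]]
            x = parent_of[x]
        return x

    chosen = []
    for (a, b), _w in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent_of[ra] = rb
            chosen.append((a, b))
        if len(chosen) == len(features) - 1:
            break
    # direct outward from the canonical root by BFS
    adj: dict[str, list[str]] = {f: [] for f in features}
    for a, b in chosen:
        adj[a].append(b)
        adj[b].append(a)
    root = features[0]
    directed = []
    visited = {root}
    queue = [root]
    while queue:
        node = queue.pop(0)
        for nb in sorted(adj[node]):
            if nb not in visited:
                visited.add(nb)
                directed.append((node, nb))
                queue.append(nb)
    return BNStructure(class_var, features, dict(n_states), tuple(directed))


# ---------------------------------------------------------------------------
# CPTs and EM


@dataclass
class BNModel:
    """Structure + CPTs + the discretization schemes that built the states.

    CPT layout: for the class, a vector of length n_class; for a feature F
    with feature parent P, an array of shape (n_class, n_P, n_F) (parent-
    major); for a root feature, (n_class, n_F).  Each trailing-axis slice
    is a conditional distribution summing to 1.
    """

    structure: BNStructure
    cpts: dict
    schemes: dict = field(default_factory=dict)
    state_labels: dict = field(default_factory=dict)

    def to_json(self) -> str:
        enc = {
            "class_var": self.structure.class_var,
            "features": list(self.structure.features),
            "n_states": {k: int(v) for k, v in self.structure.n_states.items()},
            "tree_edges": [list(e) for e in self.structure.tree_edges],
            "cpts": {k: np.asarray(v).tolist() for k, v in self.cpts.items()},
            "schemes": {k: s.to_dict() for k, s in self.schemes.items()},
            "state_labels": self.state_labels,
        }
        return json.dumps(enc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "BNModel":
        d = json.loads(text)
        structure = BNStructure(
            d["class_var"], tuple(d["features"]), d["n_states"], tuple(tuple(e) for e in d["tree_edges"])
        )
        cpts = {k: np.asarray(v, dtype=float) for k, v in d["cpts"].items()}
        schemes = {k: DiscretizationScheme.from_dict(s) for k, s in d.get("schemes", {}).items()}
        return cls(structure, cpts, schemes, d.get("state_labels", {}))


def _normalize(counts: np.ndarray) -> np.ndarray:
    total = counts.sum(axis=-1, keepdims=True)
    out = np.where(total > 0, counts / np.where(total == 0, 1, total), 1.0 / counts.shape[-1])
    return out


def _case_posterior_missing(structure, cpts, row, missing):
    """Joint posterior over the missing variables of one case, by enumeration.

    Returns (configs, probs): each config assigns states to the missing
    variables (class included if missing).
    """
    vars_missing = list(missing)
    domains = [range(structure.n_states[v]) for v in vars_missing]
    configs = list(itertools.product(*domains))
    probs = np.empty(len(configs))
    for i, cfg in enumerate(configs):
        assign = dict(row)
        assign.update(dict(zip(vars_missing, cfg)))
        probs[i] = _joint_prob(structure, cpts, assign)
    total = probs.sum()
    if total <= 0:
        probs = np.full(len(configs), 1.0 / len(configs))
    else:
        probs = probs / total
    return configs, probs


def _joint_prob(structure: BNStructure, cpts: dict, assign: dict) -> float:
    c = assign[structure.class_var]
    p = cpts[structure.class_var][c]
    for f in structure.features:
        parent = structure.feature_parent(f)
        if parent is None:
            p *= cpts[f][c, assign[f]]
        else:
            p *= cpts[f][c, assign[parent], assign[f]]
    return float(p)


def loglikelihood(structure: BNStructure, cpts: dict, data: pd.DataFrame) -> float:
    """Observed-data log-likelihood (missing values marginalized out)."""
    ll = 0.0
    cols = [structure.class_var, *structure.features]
    for _, r in data[cols].iterrows():
        row = {k: (int(v) if pd.notna(v) else None) for k, v in r.items()}
        missing = [k for k, v in row.items() if v is None]
        observed = {k: v for k, v in row.items() if v is not None}
        if not missing:
            p = _joint_prob(structure, cpts, observed)
        else:
            p = 0.0
            domains = [range(structure.n_states[v]) for v in missing]
            for cfg in itertools.product(*domains):
                assign = dict(observed)
                assign.update(dict(zip(missing, cfg)))
                p += _joint_prob(structure, cpts, assign)
        ll += np.log(max(p, 1e-300))
    return float(ll)


def _count_arrays(structure: BNStructure, alpha: float) -> dict:
    counts = {structure.class_var: np.full(structure.n_states[structure.class_var], alpha, dtype=float)}
    nc = structure.n_states[structure.class_var]
    for f in structure.features:
        parent = structure.feature_parent(f)
        if parent is None:
            counts[f] = np.full((nc, structure.n_states[f]), alpha, dtype=float)
        else:
            counts[f] = np.full((nc, structure.n_states[parent], structure.n_states[f]), alpha, dtype=float)
    return counts


def _accumulate(structure, counts, assign, weight):
    counts[structure.class_var][assign[structure.class_var]] += weight
    c = assign[structure.class_var]
    for f in structure.features:
        parent = structure.feature_parent(f)
        if parent is None:
            counts[f][c, assign[f]] += weight
        else:
            counts[f][c, assign[parent], assign[f]] += weight


def fit_cpts_em(
    structure: BNStructure,
    data: pd.DataFrame,
    alpha: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 200,
    return_history: bool = False,
):
    """EM estimation of all CPTs; complete-data rows are counted directly,
    rows with missing values contribute expected counts under the current
    posteriors.  Stops when the relative observed-data log-likelihood change
    falls below ``tol``.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    cols = [structure.class_var, *structure.features]
    arr = data[cols].to_numpy(dtype=float)
    complete_mask = ~np.isnan(arr).any(axis=1)
    comp = arr[complete_mask].astype(int)
    incomplete = []
    for row in arr[~complete_mask]:
        incomplete.append(
            {k: (int(v) if not np.isnan(v) else None) for k, v in zip(cols, row)}
        )

    base = _count_arrays(structure, alpha)
    if len(comp):
        col_idx = {k: i for i, k in enumerate(cols)}
        cvals = comp[:, 0]
        np.add.at(base[structure.class_var], cvals, 1.0)
        for f in structure.features:
            parent = structure.feature_parent(f)
            fvals = comp[:, col_idx[f]]
            if parent is None:
                np.add.at(base[f], (cvals, fvals), 1.0)
            else:
                np.add.at(base[f], (cvals, comp[:, col_idx[parent]], fvals), 1.0)

    cpts = {k: _normalize(v) for k, v in base.items()}
    history = [loglikelihood(structure, cpts, data)] if (incomplete or return_history) else []

    if not incomplete:
        if any(np.any(v.sum(axis=-1) == 0) for v in base.values()) and alpha == 0:
            import warnings

            warnings.warn("empty parent configuration with alpha=0; uniform fallback")
        return (cpts, history) if return_history else cpts

    for _ in range(max_iter):
        counts = {k: v.copy() for k, v in base.items()}
        for r in incomplete:
            missing = [k for k, v in r.items() if v is None]
            observed = {k: v for k, v in r.items() if v is not None}
            configs, probs = _case_posterior_missing(structure, cpts, observed, missing)
            for cfg, w in zip(configs, probs):
                assign = dict(observed)
                assign.update(dict(zip(missing, cfg)))
                _accumulate(structure, counts, assign, float(w))
        cpts = {k: _normalize(v) for k, v in counts.items()}
        ll = loglikelihood(structure, cpts, data)
        prev = history[-1]
        history.append(ll)
        if abs(ll - prev) <= tol * max(abs(prev), 1.0):
            break
    return (cpts, history) if return_history else cpts


# ---------------------------------------------------------------------------
# Inference


def posterior_flight(model: BNModel, evidence: dict) -> np.ndarray:
    """Exact posterior over the class states given partial evidence.

    ``evidence`` maps feature name -> state index (int) for any subset of
    features; unknown features or state labels raise.  Returns a length-
    n_class probability vector (index 1 = flight true under the default
    state coding).
    """
    s = model.structure
    for var, st in evidence.items():
        if var not in s.features:
            raise KeyError(f"unknown feature {var!r}")
        if not 0 <= int(st) < s.n_states[var]:
            raise KeyError(f"unknown state {st!r} for feature {var!r}")
    nc = s.n_states[s.class_var]
    children = s.children
    like = np.ones(nc)
    for c in range(nc):

        def message(f: str, parent_state: int | None) -> float:
            parent = s.feature_parent(f)
            if parent is None:
                dist = model.cpts[f][c]
            else:
                dist = model.cpts[f][c, parent_state]
            states = [int(evidence[f])] if f in evidence else range(s.n_states[f])
            total = 0.0
            for x in states:
                term = dist[x]
                for ch in children[f]:
                    term *= message(ch, x)
                total += term
            return total

        for root in s.roots:
            like[c] *= message(root, None)
    joint = model.cpts[s.class_var] * like
    total = joint.sum()
    if total <= 0:
        return np.full(nc, 1.0 / nc)
    return joint / total


def score_cases(model: BNModel, data: pd.DataFrame) -> np.ndarray:
    """P(flight = true) per case, vectorized over fully observed rows.

    Rows with missing covariates are handled by exact marginalization via
    :func:`posterior_flight`.  ``data`` holds integer state codes (pandas
    NA for missing) in the model's feature columns.
    """
    s = model.structure
    cols = list(s.features)
    arr = data[cols].to_numpy(dtype=float)
    n = len(arr)
    out = np.empty(n)
    full = ~np.isnan(arr).any(axis=1)
    if full.any():
        comp = arr[full].astype(int)
        nc = s.n_states[s.class_var]
        logp = np.tile(np.log(np.clip(model.cpts[s.class_var], 1e-300, None)), (comp.shape[0], 1))
        col_idx = {k: i for i, k in enumerate(cols)}
        for f in s.features:
            parent = s.feature_parent(f)
            fv = comp[:, col_idx[f]]
            for c in range(nc):
                if parent is None:
                    logp[:, c] += np.log(np.clip(model.cpts[f][c, fv], 1e-300, None))
                else:
                    pv = comp[:, col_idx[parent]]
                    logp[:, c] += np.log(np.clip(model.cpts[f][c, pv, fv], 1e-300, None))
        logp -= logp.max(axis=1, keepdims=True)
        p = np.exp(logp)
        p /= p.sum(axis=1, keepdims=True)
        out[full] = p[:, 1]
    for i in np.nonzero(~full)[0]:
        evidence = {
            f: int(arr[i, j]) for j, f in enumerate(cols) if not np.isnan(arr[i, j])
        }
        out[i] = posterior_flight(model, evidence)[1]
    return out


def model_summary(model: BNModel) -> dict:
    """Node/linkage/probability counts as reported for fitted networks."""
    s = model.structure
    n_nodes = 1 + len(s.features)
    n_linkages = len(s.features) + len(s.tree_edges)
    nc = s.n_states[s.class_var]
    n_prob = nc
    for f in s.features:
        parent = s.feature_parent(f)
        parent_combos = nc * (s.n_states[parent] if parent is not None else 1)
        n_prob += parent_combos * s.n_states[f]
    return {"n_nodes": n_nodes, "n_linkages": n_linkages, "n_probabilities": n_prob}
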