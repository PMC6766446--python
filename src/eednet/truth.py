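"""Ground-truth causal structure for the synthetic cohort.

A :class:`TruthDAG` stores the standardized coefficients the simulator uses to
generate data, in exactly the units the network estimator later reports:
effects per 1 SD of the (transformed, standardized) parent on the linear scale
for continuous children and on the log-odds scale for binary children.  It is
the recovery target for every parameter-recovery test.

Arcs are restricted to the hypothesized layer order

    diet densities -> {MPO, NEO, AAT, LMZ, AGP} -> deficiency outcomes

plus direct diet -> outcome arcs, AGP -> outcome arcs, and the four
deficiency-outcome -> anemia arcs, which keeps any truth graph acyclic by
construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .config import EED_NODES, INFLAMMATION_NODE, OUTCOME_NODES

__all__ = ["TruthDAG", "truth_table", "layer_of", "arc_allowed"]

ANEMIA_PARENT_OUTCOMES = ["low_ferritin", "high_tfr", "low_retinol", "low_zinc"]


def layer_of(node: str) -> str:
    """Classify a node name into diet / eed / inflammation / outcome."""
    if node.startswith("diet_"):
        return "diet"
    if node in EED_NODES:
        return "eed"
    if node == INFLAMMATION_NODE:
        return "inflammation"
    if node in OUTCOME_NODES:
        return "outcome"
    raise KeyError(f"unknown node {node!r}")


def arc_allowed(parent: str, child: str) -> bool:
    """Whether parent -> child respects the hypothesized layer order."""
    lp, lc = layer_of(parent), layer_of(child)
    if lp == "diet":
        return lc in ("eed", "inflammation", "outcome")
    if lp in ("eed", "inflammation"):
        return lc == "outcome"
    if lp == "outcome":
        return child == "anemia" and parent in ANEMIA_PARENT_OUTCOMES
    return False


@dataclass
class TruthDAG:
    """Arcs with true standardized coefficients plus node metadata.

    node_families maps each non-root node to ``("linear", sigma)`` or
    ``("logistic", None)``; sigma may be None, meaning "set the residual SD to
    sqrt(max(0.05, 1 - sum(beta^2)))" so the child is approximately unit-SD.
    intercepts maps node -> {site: intercept} (log-odds scale for logistic
    nodes, latent scale for linear nodes); missing entries default to 0.
    """

    arcs: list[tuple[str, str, float]] = field(default_factory=list)
    node_families: dict[str, tuple[str, float | None]] = field(default_factory=dict)
    intercepts: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        g = nx.DiGraph()
        for parent, child, _ in self.arcs:
            if not arc_allowed(parent, child):
                raise ValueError(f"arc {parent} -> {child} violates the layer order")
            g.add_edge(parent, child)
        if not nx.is_directed_acyclic_graph(g):  # defensive; layering implies acyclic
            raise ValueError("truth graph is cyclic")
        for _, child, _ in self.arcs:
            if child not in self.node_families:
                raise ValueError(f"no family declared for child node {child!r}")

    @property
    def nodes(self) -> list[str]:
        seen: dict[str, None] = {}
        for p, c, _ in self.arcs:
            seen.setdefault(p)
            seen.setdefault(c)
        for n in self.node_families:
            seen.setdefault(n)
        return list(seen)

    def parents(self, node: str) -> list[tuple[str, float]]:
        return [(p, b) for p, c, b in self.arcs if c == node]

    def family(self, node: str) -> str:
        if node in self.node_families:
            return self.node_families[node][0]
        return "linear"

    def residual_sd(self, node: str) -> float:
        fam, sigma = self.node_families.get(node, ("linear", None))
        if fam != "linear":
            raise ValueError(f"{node!r} is not a linear node")
        if sigma is not None:
            return float(sigma)
        ss = sum(b * b for _, b in self.parents(node))
        return math.sqrt(max(0.05, 1.0 - ss))

    def intercept(self, node: str, site: str) -> float:
        return float(self.intercepts.get(node, {}).get(site, 0.0))

    def coefficient(self, parent: str, child: str) -> float:
        for p, c, b in self.arcs:
            if p == parent and c == child:
                return float(b)
        return 0.0

    def topological_children(self) -> list[str]:
        """Non-root nodes in generation order (EED/AGP layer, then outcomes)."""
        children = [n for n in self.node_families]
        order = {"eed": 0, "inflammation": 0, "outcome": 1}
        non_anemia = sorted(
            (n for n in children if n != "anemia"), key=lambda n: order[layer_of(n)]
        )
        return non_anemia + (["anemia"] if "anemia" in children else [])


def truth_table(truth: TruthDAG) -> pd.DataFrame:
    """One row per arc: true coefficient and, for logistic children, true OR."""
    rows = []
    for parent, child, beta in truth.arcs:
        fam = truth.family(child)
        rows.append({
            "parent": parent,
            "child": child,
            "family": fam,
            "beta_true": float(beta),
            "or_true": math.exp(beta) if fam == "logistic" else float("nan"),
        })
    return pd.DataFrame(rows, columns=["parent", "child", "family", "beta_true", "or_true"])


def default_truth(calibration: dict | None = None, sites: list[str] | None = None) -> TruthDAG:
    """A study-shaped default truth: modest protective diet -> EED arcs, modest
    EED -> deficiency arcs, inflammation effects, and outcome -> anemia arcs.

    Outcome intercepts are set from the calibrated per-site prevalence targets
    (logit of the target), so marginal prevalences land near the calibration
    when arc effects are small.
    """
    from .config import load_calibration

    cal = calibration or load_calibration()
    sites = sites or list(cal["sites"])
    arcs: list[tuple[str, str, float]] = [
        ("diet_zinc", "lmz", -0.14),
        ("diet_calcium", "mpo", -0.15),
        ("diet_calcium", "aat", -0.19),
        ("diet_vitamin_a", "mpo", -0.12),
        ("diet_vitamin_a", "neo", -0.14),
        ("diet_vitamin_a", "aat", -0.21),
        ("diet_vitamin_b6", "mpo", -0.10),
        ("diet_protein", "mpo", -0.12),
        ("diet_protein", "aat", -0.14),
        ("diet_vitamin_b12", "mpo", 0.10),
        ("lmz", "anemia", math.log(1.15)),
        ("mpo", "anemia", math.log(1.16)),
        ("aat", "low_ferritin", math.log(1.19)),
        ("neo", "low_ferritin", math.log(1.22)),
        ("lmz", "low_retinol", math.log(1.24)),
        ("neo", "low_retinol", math.log(0.75)),
        ("mpo", "high_tfr", math.log(0.86)),
        ("aat", "low_zinc", math.log(0.83)),
        ("diet_iron", "low_ferritin", math.log(0.73)),
        ("diet_iron", "high_tfr", math.log(0.79)),
        ("diet_iron", "low_retinol", math.log(0.74)),
        ("diet_calcium", "high_tfr", math.log(1.28)),
        ("diet_vitamin_a", "anemia", math.log(1.52)),
        ("agp", "low_retinol", math.log(1.58)),
        ("agp", "high_tfr", math.log(1.18)),
        ("agp", "anemia", math.log(1.29)),
        ("agp", "low_ferritin", math.log(0.62)),
        ("low_ferritin", "anemia", math.log(2.79)),
        ("low_retinol", "anemia", math.log(1.58)),
        ("high_tfr", "anemia", math.log(2.26)),
        ("low_zinc", "anemia", math.log(0.93)),
    ]
    families: dict[str, tuple[str, float | None]] = {
        n: ("linear", None) for n in EED_NODES + [INFLAMMATION_NODE]
    }
    families.update({n: ("logistic", None) for n in OUTCOME_NODES})
    intercepts = {
        out: {s: math.log(p / (1 - p)) for s, p in cal["prevalence"][out].items() if s in sites}
        for out in OUTCOME_NODES
    }
    return TruthDAG(arcs=arcs, node_families=families, intercepts=intercepts)


def null_truth(sites: list[str] | None = None, prevalence: float = 0.3) -> TruthDAG:
    """All-arcs-zero truth with flat outcome prevalence (for null simulations)."""
    from .config import load_calibration

    sites = sites or list(load_calibration()["sites"])
    families: dict[str, tuple[str, float | None]] = {
        n: ("linear", None) for n in EED_NODES + [INFLAMMATION_NODE]
    }
    families.update({n: ("logistic", None) for n in OUTCOME_NODES})
    alpha = math.log(prevalence / (1 - prevalence))
    intercepts = {out: {s: alpha for s in sites} for out in OUTCOME_NODES}
    return TruthDAG(arcs=[], node_families=families, intercepts=intercepts)
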