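"""Packaged case fixture and synthetic problem generation.

Ships the four-victim, ten-criterion ambulance-dispatch decision matrix as
a reproducible fixture, and generates random decision problems plus
*consistent* simulated decision makers — a hidden weight vector drawn from
the ranking-constrained simplex that answers every tradeoff question
exactly — so the elicitation loop can be exercised end to end without any
external data.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .decision_model import Alternative, ConsequenceMatrix, Criterion
from .elicitation import TradeoffQuestion

#: default scale mix for generated problems: mostly 4-level ordinal scales
#: (as in the dispatch case, where 8 of 10 criteria are verbal 1-4 scales)
#: with occasional continuous criteria.
DEFAULT_ORDINAL_SHARE = 0.8
DEFAULT_CONTINUOUS_BOUNDS = (0.0, 100.0)


@dataclass(frozen=True)
class ProblemFixture:
    """A complete decision problem: ranked criteria plus consequence matrix."""

    criteria: tuple[Criterion, ...]
    matrix: ConsequenceMatrix
    provenance: str = ""

    def __post_init__(self) -> None:
        if tuple(self.criteria) != self.matrix.criteria:
            raise ValueError("fixture criteria must match the matrix criteria")
        object.__setattr__(self, "criteria", tuple(self.criteria))


def samu_fixture() -> ProblemFixture:
    """The four-victim emergency-dispatch instance.

    Ten ranked criteria — airways and oxygenation first, then state of
    consciousness, pulse, trauma, health history, access to healthcare,
    access to the victim's location, social commotion, distance (km) and
    age — and four victims described on those scales.  Loaded from the
    packaged CSV/YAML data files.
    """
    from .io import read_problem

    data = resources.files("fitradeoff").joinpath("data")
    with resources.as_file(data.joinpath("samu_matrix.csv")) as mpath, resources.as_file(
        data.joinpath("samu_criteria.yaml")
    ) as cpath:
        fixture = read_problem(mpath, cpath)
    return ProblemFixture(
        criteria=fixture.criteria,
        matrix=fixture.matrix,
        provenance="packaged SAMU/192 four-victim dispatch case",
    )


def random_problem(
    n_alternatives: int,
    k_criteria: int,
    scale_spec: str | list[dict] | None = None,
    seed: int = 0,
) -> ProblemFixture:
    """Generate a random, always-valid decision problem.

    ``scale_spec`` is ``"mixed"`` (default: each criterion is a 1-4
    ordinal scale with probability 0.8, else continuous on [0, 100]),
    ``"ordinal"`` (all 1-4 ordinal), ``"continuous"``, or an explicit list
    of per-criterion mappings with keys ``scale_kind``, ``scale_min``,
    ``scale_max``, ``n_levels`` and optionally ``direction``.  Criterion
    ranks are a random permutation; everything is reproducible by seed.
    """
    if n_alternatives < 2 or k_criteria < 2:
        raise ValueError("need at least 2 alternatives and 2 criteria")
    rng = np.random.default_rng(seed)
    if scale_spec is None:
        scale_spec = "mixed"
    if isinstance(scale_spec, str):
        if scale_spec not in ("mixed", "ordinal", "continuous"):
            raise ValueError(f"unknown scale_spec {scale_spec!r}")
        specs = []
        for _ in range(k_criteria):
            ordinal = scale_spec == "ordinal" or (
                scale_spec == "mixed" and rng.random() < DEFAULT_ORDINAL_SHARE
            )
            if ordinal:
                specs.append({"scale_kind": "ordinal", "scale_min": 1, "scale_max": 4, "n_levels": 4})
            else:
                lo, hi = DEFAULT_CONTINUOUS_BOUNDS
                specs.append({"scale_kind": "continuous", "scale_min": lo, "scale_max": hi})
    else:
        specs = [dict(s) for s in scale_spec]
        if len(specs) != k_criteria:
            raise ValueError("scale_spec list length must equal k_criteria")
    ranks = rng.permutation(k_criteria) + 1
    criteria = []
    for j, spec in enumerate(specs):
        direction = spec.get("direction") or ("maximize" if rng.random() < 0.5 else "minimize")
        criteria.append(
            Criterion(
                id=f"c{j+1}",
                name=f"criterion {j+1}",
                direction=direction,
                scale_kind=spec["scale_kind"],
                scale_min=spec.get("scale_min"),
                scale_max=spec.get("scale_max"),
                n_levels=spec.get("n_levels"),
                rank=int(ranks[j]),
            )
        )
    x = np.empty((n_alternatives, k_criteria))
    for j, crit in enumerate(criteria):
        if crit.scale_kind == "ordinal":
            x[:, j] = rng.integers(int(crit.scale_min), int(crit.scale_max) + 1, n_alternatives)
        else:
            x[:, j] = rng.uniform(crit.scale_min, crit.scale_max, n_alternatives)
    alternatives = tuple(
        Alternative(id=f"a{i+1}", label=f"alternative {i+1}") for i in range(n_alternatives)
    )
    matrix = ConsequenceMatrix(alternatives=alternatives, criteria=tuple(criteria), x=x)
    return ProblemFixture(
        criteria=tuple(criteria), matrix=matrix, provenance=f"random_problem(seed={seed})"
    )


@dataclass(frozen=True)
class SimulatedDM:
    """A consistent decision maker holding a hidden true weight vector.

    ``true_weights`` are indexed by rank (position 0 = most important
    criterion), non-increasing, and sum to one — hence always feasible in
    the ranking-constrained simplex.  Questions are answered by exact
    comparison of the two hypothetical consequences' additive values,
    ``w_a * v_a(test_level)`` versus ``w_b``.
    """

    true_weights: tuple[float, ...]

    def __post_init__(self) -> None:
        w = np.asarray(self.true_weights, dtype=float)
        if np.any(np.diff(w) > 1e-12) or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("true_weights must be non-increasing, nonnegative, sum 1")

    def answer(self, question: TradeoffQuestion) -> str:
        w_a = self.true_weights[question.pair_rank - 1]
        w_b = self.true_weights[question.pair_rank]
        value_a = question.v_test * w_a
        if value_a > w_b:
            return "prefer_a"
        if value_a < w_b:
            return "prefer_b"
        return "indifferent"

    __call__ = answer

    def weights_for(self, criteria) -> np.ndarray:
        """True weights re-indexed to a criteria list's own order."""
        out = np.empty(len(criteria))
        for j, crit in enumerate(criteria):
            out[j] = self.true_weights[crit.rank - 1]
        return out


def simulated_dm(k: int, seed: int = 0) -> SimulatedDM:
    """Draw a simulated DM whose weights are uniform over the
    ranking-constrained simplex (a sorted flat-Dirichlet sample)."""
    rng = np.random.default_rng(seed)
    w = np.sort(rng.dirichlet(np.ones(k)))[::-1]
    return SimulatedDM(true_weights=tuple(float(v) for v in w))
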