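"""Synthetic multi-cohort expression studies with planted ground truth.

The generator emulates the situation the pair-feature method is built
for: several case/control cohorts measured on different platforms, whose
absolute expression values are incomparable (per-cohort per-gene additive
shifts, per-sample monotone distortions) but whose within-sample gene
orderings carry the signal.  Signal is planted as *reversed pairs*: for a
planted pair (a, b) the probability that gene a exceeds gene b within a
sample differs between cases and controls.  Survival times for cases
follow an exponential proportional-hazards model on the realized pair
features, so the prognostic stage has recoverable ground truth as well.

Generative model, per cohort:

1. baseline gene means ``mu_g ~ Normal(8, 2)`` (log2 scale, shared across
   cohorts); per-sample expression ``Normal(mu_g, 1)``;
2. per-cohort per-gene batch offset ``Normal(0, batch_shift_sd)``;
3. planted reversals: for each planted pair and sample, with the
   group-specific reversal probability set ``g_a > g_b`` by a margin
   ``delta ~ Uniform(0.5, 1.5)`` around the pair's current mid-point,
   otherwise ``g_a < g_b`` by the same construction.  Reversals are
   imposed after the batch offsets so the configured rates are the rates
   actually realized in the observable data — they are the ground truth
   recovery tests check against;
4. per-sample distortion: none, affine (``a*x + b`` with
   ``a ~ Uniform(0.5, 2)``, ``b ~ Uniform(-2, 2)``) or a strictly
   increasing piecewise-linear map with 5 random interior knots;
5. genes are partitioned into pathways of equal size, with both genes of
   every planted pair co-located in one pathway;
6. for each case, survival ``time ~ Exponential(rate)`` with
   ``rate = baseline_rate * exp(sum_p beta_p * r_p)`` on the realized
   pair features, censored at ``Uniform(0, censor_time_max)``.

A single seed drives named substreams (means, noise, batch, planted,
distortion, survival), so changing one stage's parameters never shifts
the draws of another, and regeneration is bit-identical.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    ExpressionMatrix,
    GeneSet,
    write_expression,
    write_gmt,
    write_labels,
    write_survival,
)
from .pairs import GenePair, relative_expression

__all__ = [
    "PlantedPair",
    "SurvivalConfig",
    "SyntheticConfig",
    "SyntheticStudy",
    "generate_study",
    "write_fixtures",
]

_STREAMS = ("means", "noise", "batch", "planted", "distortion", "survival")


@dataclass(frozen=True)
class PlantedPair:
    """A pair with group-specific P(g_a > g_b), i.e. P(pair feature = +1)."""

    gene_a: str
    gene_b: str
    rate_case: float
    rate_control: float

    def __post_init__(self) -> None:
        if self.gene_a >= self.gene_b:
            raise ValueError(f"planted pair ({self.gene_a}, {self.gene_b}) must be in canonical order")
        for r in (self.rate_case, self.rate_control):
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"reversal rate {r} outside [0, 1]")

    @property
    def pair(self) -> GenePair:
        return GenePair(self.gene_a, self.gene_b)


@dataclass(frozen=True)
class SurvivalConfig:
    """Exponential PH model on pair features for case samples.

    ``censor_time_max=None`` disables censoring entirely (useful for
    checking estimators whose censoring handling should vanish).
    """

    baseline_rate: float = 0.25
    betas: tuple[tuple[str, str, float], ...] = ()  # (gene_a, gene_b, beta)
    censor_time_max: float | None = 12.0

    def __post_init__(self) -> None:
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be positive")
        if self.censor_time_max is not None and self.censor_time_max <= 0:
            raise ValueError("censor_time_max must be positive or None")

    @property
    def beta_map(self) -> dict[GenePair, float]:
        return {GenePair.make(a, b): float(v) for a, b, v in self.betas}


@dataclass(frozen=True)
class SyntheticConfig:
    n_cohorts: int = 3
    cases_per_cohort: int = 50
    controls_per_cohort: int = 50
    n_genes: int = 120
    n_pathways: int = 6
    genes_per_pathway: int = 20
    planted_pairs: tuple[PlantedPair, ...] = ()
    batch_shift_sd: float = 2.0
    sample_distortion: str = "none"  # none | affine | monotone
    survival: SurvivalConfig | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cohorts", "cases_per_cohort", "controls_per_cohort", "n_genes",
                     "n_pathways", "genes_per_pathway"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.batch_shift_sd < 0:
            raise ValueError("batch_shift_sd must be >= 0")
        if self.sample_distortion not in ("none", "affine", "monotone"):
            raise ValueError(f"unknown sample_distortion {self.sample_distortion!r}")
        if self.n_pathways * self.genes_per_pathway != self.n_genes:
            raise ValueError(
                "n_pathways * genes_per_pathway must equal n_genes "
                f"({self.n_pathways} * {self.genes_per_pathway} != {self.n_genes})"
            )
        genes = set(self.gene_ids)
        for pp in self.planted_pairs:
            if pp.gene_a not in genes or pp.gene_b not in genes:
                raise ValueError(f"planted pair ({pp.gene_a}, {pp.gene_b}) uses genes outside the matrix")
        if self.survival is not None:
            for a, b, _ in self.survival.betas:
                if a not in genes or b not in genes:
                    raise ValueError(f"survival beta pair ({a}, {b}) uses genes outside the matrix")

    @property
    def gene_ids(self) -> list[str]:
        width = max(4, len(str(self.n_genes)))
        return [f"G{i:0{width}d}" for i in range(1, self.n_genes + 1)]


@dataclass(frozen=True)
class Truth:
    planted_pairs: tuple[PlantedPair, ...]
    survival_betas: dict
    seed: int


@dataclass
class SyntheticStudy:
    cohorts: list[tuple[ExpressionMatrix, pd.Series]]
    survival: pd.DataFrame | None  # cases only, indexed by "<cohort>:<sample>"
    gene_sets: dict[str, GeneSet]
    truth: Truth
    config: SyntheticConfig


def _assign_pathways(config: SyntheticConfig) -> dict[str, GeneSet]:
    """Partition genes into equal pathways, co-locating each planted pair.

    Genes linked (transitively) through planted pairs must share a
    pathway, so connected components are placed first.
    """
    genes = config.gene_ids
    parent: dict[str, str] = {}

    def find(g: str) -> str:
        while parent.setdefault(g, g) != g:
            parent[g] = parent[parent[g]]
            g = parent[g]
        return g

    for pp in config.planted_pairs:
        ra, rb = find(pp.gene_a), find(pp.gene_b)
        if ra != rb:
            parent[ra] = rb
    comps: dict[str, list[str]] = {}
    for g in genes:
        comps.setdefault(find(g), []).append(g)
    # Large components (planted clusters) first, then balanced assignment:
    # spreading planted pairs over pathways keeps cross-pairs between
    # distinct planted pairs out of the candidate set (planting induces
    # genuine secondary signal in such cross-pairs).
    blocks = sorted(comps.values(), key=lambda c: (-len(c), c[0]))
    cap = config.genes_per_pathway
    pathways: list[list[str]] = [[] for _ in range(config.n_pathways)]
    for block in blocks:
        if len(block) > cap:
            raise ValueError(
                f"planted pairs link {len(block)} genes which exceeds genes_per_pathway={cap}; "
                "they cannot be co-assigned to one pathway"
            )
        candidates = [i for i, pw in enumerate(pathways) if len(pw) + len(block) <= cap]
        if not candidates:
            raise ValueError("planted pairs cannot be packed into the configured pathways")
        home = min(candidates, key=lambda i: (len(pathways[i]), i))
        pathways[home].extend(block)
    width = max(2, len(str(config.n_pathways)))
    return {
        f"PW{i:0{width}d}": GeneSet(f"synthetic pathway {i}", tuple(sorted(pw)))
        for i, pw in enumerate(pathways, start=1)
    }


def _monotone_map(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Strictly increasing piecewise-linear map with 5 random interior knots."""
    lo, hi = float(x.min()) - 1.0, float(x.max()) + 1.0
    inner = np.sort(rng.uniform(lo, hi, size=5))
    xk = np.concatenate(([lo], inner, [hi]))
    xk = np.unique(xk)  # uniform draws collide with probability 0
    slopes = rng.uniform(0.2, 2.0, size=xk.size)
    yk = np.concatenate(([0.0], np.cumsum(np.diff(xk) * slopes[1:])))
    yk += rng.uniform(-2.0, 2.0)
    return np.interp(x, xk, yk)


def generate_study(config: SyntheticConfig) -> SyntheticStudy:
    """Generate a full multi-cohort study with ground truth."""
    ss = np.random.SeedSequence(config.seed)
    rngs = {name: np.random.Generator(np.random.PCG64(child))
            for name, child in zip(_STREAMS, ss.spawn(len(_STREAMS)))}

    genes = config.gene_ids
    gene_pos = {g: i for i, g in enumerate(genes)}
    mu = rngs["means"].normal(8.0, 2.0, size=config.n_genes)

    n_per = config.cases_per_cohort + config.controls_per_cohort
    swidth = max(3, len(str(n_per)))
    cohorts: list[tuple[ExpressionMatrix, pd.Series]] = []
    surv_rows: dict[str, tuple[float, int]] = {}
    beta_map = config.survival.beta_map if config.survival is not None else {}

    for c in range(1, config.n_cohorts + 1):
        cid = f"cohort{c}"
        X = mu[:, None] + rngs["noise"].normal(0.0, 1.0, size=(config.n_genes, n_per))
        # per-cohort per-gene technical shift (platform / batch effect)
        X += rngs["batch"].normal(0.0, config.batch_shift_sd, size=config.n_genes)[:, None]

        sample_ids = [f"s{k:0{swidth}d}" for k in range(1, n_per + 1)]
        labels = np.array([1] * config.cases_per_cohort + [0] * config.controls_per_cohort,
                          dtype=np.int8)

        for pp in config.planted_pairs:
            ia, ib = gene_pos[pp.gene_a], gene_pos[pp.gene_b]
            rates = np.where(labels == 1, pp.rate_case, pp.rate_control)
            up = rngs["planted"].random(n_per) < rates
            delta = rngs["planted"].uniform(0.5, 1.5, size=n_per)
            centre = 0.5 * (X[ia] + X[ib])
            sign = np.where(up, 1.0, -1.0)
            X[ia] = centre + sign * delta / 2.0
            X[ib] = centre - sign * delta / 2.0

        if config.sample_distortion == "affine":
            a = rngs["distortion"].uniform(0.5, 2.0, size=n_per)
            b = rngs["distortion"].uniform(-2.0, 2.0, size=n_per)
            X = X * a[None, :] + b[None, :]
        elif config.sample_distortion == "monotone":
            for k in range(n_per):
                X[:, k] = _monotone_map(X[:, k], rngs["distortion"])

        expr = ExpressionMatrix(pd.DataFrame(X, index=genes, columns=sample_ids), cohort_id=cid)
        lab = pd.Series(labels, index=sample_ids, name="label")
        cohorts.append((expr, lab))

        if config.survival is not None:
            for k in range(config.cases_per_cohort):
                lp = 0.0
                for pair, beta in beta_map.items():
                    r = relative_expression(X[gene_pos[pair.gene_a], k], X[gene_pos[pair.gene_b], k])
                    lp += beta * r
                rate = config.survival.baseline_rate * math.exp(lp)
                t_event = rngs["survival"].exponential(1.0 / rate)
                if config.survival.censor_time_max is None:
                    t_obs, event = t_event, 1
                else:
                    t_cens = rngs["survival"].uniform(0.0, config.survival.censor_time_max)
                    t_obs, event = min(t_event, t_cens), int(t_event <= t_cens)
                surv_rows[f"{cid}:{sample_ids[k]}"] = (t_obs, event)

    survival = None
    if config.survival is not None:
        survival = pd.DataFrame(
            {"time": [v[0] for v in surv_rows.values()],
             "event": [v[1] for v in surv_rows.values()]},
            index=list(surv_rows),
        )
        survival.index.name = "sample_id"

    truth = Truth(
        planted_pairs=config.planted_pairs,
        survival_betas={str(p): b for p, b in beta_map.items()},
        seed=config.seed,
    )
    return SyntheticStudy(cohorts, survival, _assign_pathways(config), truth, config)


def write_fixtures(study: SyntheticStudy, directory: str | Path) -> dict[str, Path]:
    """Write the study as a complete on-disk fixture set.

    One expression TSV and one labels TSV per cohort, a combined survival
    table keyed by prefixed sample ids, the pathway GMT, and a JSON truth
    file listing the planted structure.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out: dict[str, Path] = {}
    for expr, labels in study.cohorts:
        p_expr = directory / f"expr_{expr.cohort_id}.tsv"
        p_lab = directory / f"labels_{expr.cohort_id}.tsv"
        write_expression(expr, p_expr)
        write_labels(labels, p_lab)
        out[f"expr_{expr.cohort_id}"] = p_expr
        out[f"labels_{expr.cohort_id}"] = p_lab
    if study.survival is not None:
        p_surv = directory / "survival.tsv"
        write_survival(study.survival, p_surv)
        out["survival"] = p_surv
    p_gmt = directory / "pathways.gmt"
    write_gmt(study.gene_sets, p_gmt)
    out["gene_sets"] = p_gmt
    p_truth = directory / "truth.json"
    truth = {
        "seed": study.truth.seed,
        "planted_pairs": [
            {"gene_a": pp.gene_a, "gene_b": pp.gene_b,
             "rate_case": pp.rate_case, "rate_control": pp.rate_control}
            for pp in study.truth.planted_pairs
        ],
        "survival_betas": study.truth.survival_betas,
    }
    p_truth.write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    out["truth"] = p_truth
    return out
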