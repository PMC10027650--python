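"""Weighted sense-of-agency (SoA) scoring with invariance checks.

After each induction block, participants rate agreement with questionnaire
items on a 0-100 visual-analogue scale.  Because a plain item average is a
poor indicator of a latent construct, scores are computed as a *weighted*
sum: each item is weighted by its loading on the first principal component
of the pooled (condition-general) item correlation matrix, a proxy for the
latent SoA variable.

Using one loading vector across conditions presumes measurement
invariance; this is checked with Tucker's congruence coefficient

    phi(x, y) = sum(x_i y_i) / sqrt(sum(x_i^2) * sum(y_i^2))

between the condition-general loadings and loadings re-estimated within
each condition.  Conventional interpretation markers are .85 (fair) and
.95 (good similarity); by default the check only reports the coefficients.

A seeded one-factor response generator supports parameter-recovery tests:
``response = clamp(mu_c + lambda_j * eta_ic + eps_ijc, 0, 100)`` with
independent Gaussian latent scores and item noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .manipulators import CONDITIONS

#: Congruence interpretation markers (report-only by default).
CONGRUENCE_FAIR = 0.85
CONGRUENCE_GOOD = 0.95

#: Default per-condition latent means on the VAS scale, ordered to mirror
#: the qualitative pattern baseline < pose-only < expression-only <= both.
DEFAULT_CONDITION_MEANS: dict[str, float] = {"B": 40.0, "P": 62.0, "E": 74.0, "PE": 78.0}

#: Default item loadings (VAS units per latent SD) for a 4-item scale.
DEFAULT_LOADINGS = np.array([18.0, 22.0, 20.0, 15.0])


@dataclass
class ResponseMatrix:
    """Questionnaire responses: participants x items x conditions, 0-100."""

    values: np.ndarray
    items: list[str]
    conditions: list[str]
    participants: Optional[list] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be (participants, items, conditions)")
        n_p, n_i, n_c = self.values.shape
        if n_i != len(self.items) or n_c != len(self.conditions):
            raise ValueError("label lengths must match value dimensions")
        if n_i < 2:
            raise ValueError("need at least 2 items")
        if n_p < 3:
            raise ValueError("need at least 3 participants")
        if np.any(self.values < 0) or np.any(self.values > 100):
            raise ValueError("responses must lie in [0, 100]")
        unknown = set(self.conditions) - set(CONDITIONS)
        if unknown:
            raise ValueError(f"unknown condition labels: {sorted(unknown)}")
        if self.participants is None:
            self.participants = list(range(1, n_p + 1))

    @property
    def n_participants(self) -> int:
        return self.values.shape[0]

    def pooled(self, within_condition_center: bool = False) -> np.ndarray:
        """Rows = participant-condition pairs, columns = items.

        With ``within_condition_center`` each condition's item means are
        removed before stacking, so the pooled matrix carries only
        within-condition (co)variation — the relevant structure for
        estimating a common loading pattern while conditions differ in mean.
        """
        n_p, n_i, n_c = self.values.shape
        values = self.values
        if within_condition_center:
            values = values - values.mean(axis=0, keepdims=True)
        return values.transpose(0, 2, 1).reshape(n_p * n_c, n_i)

    def condition(self, label: str) -> np.ndarray:
        """Rows = participants, columns = items, for one condition."""
        return self.values[:, :, self.conditions.index(label)]

    # -- long-format CSV (participant,condition,item,value) ---------------

    def to_long(self) -> pd.DataFrame:
        rows = []
        for pi, participant in enumerate(self.participants):
            for ci, cond in enumerate(self.conditions):
                for ii, item in enumerate(self.items):
                    rows.append(
                        {
                            "participant": participant,
                            "condition": cond,
                            "item": item,
                            "value": self.values[pi, ii, ci],
                        }
                    )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_long().to_csv(path, index=False)

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "ResponseMatrix":
        required = {"participant", "condition", "item", "value"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"long-format table missing columns: {sorted(missing)}")
        participants = sorted(df["participant"].unique())
        items = sorted(df["item"].unique())
        conditions = [c for c in CONDITIONS if c in set(df["condition"])]
        values = np.full((len(participants), len(items), len(conditions)), np.nan)
        p_idx = {p: i for i, p in enumerate(participants)}
        i_idx = {it: i for i, it in enumerate(items)}
        c_idx = {c: i for i, c in enumerate(conditions)}
        for row in df.itertuples(index=False):
            values[p_idx[row.participant], i_idx[row.item], c_idx[row.condition]] = row.value
        if np.isnan(values).any():
            raise ValueError("incomplete response table (missing cells)")
        return cls(values=values, items=items, conditions=conditions,
                   participants=participants)

    @classmethod
    def from_csv(cls, path) -> "ResponseMatrix":
        return cls.from_long(pd.read_csv(path))


@dataclass(frozen=True)
class LoadingVector:
    """First-component loadings per item, with provenance."""

    loadings: np.ndarray
    items: tuple[str, ...]
    scope: str = "condition-general"

    def __post_init__(self) -> None:
        object.__setattr__(self, "loadings", np.asarray(self.loadings, dtype=float))
        if self.loadings.ndim != 1 or self.loadings.size != len(self.items):
            raise ValueError("loadings must be one value per item")
        if np.allclose(self.loadings, 0):
            raise ValueError("loading vector must not be all zero")


def _first_component_loadings(rows: np.ndarray, items: Sequence[str]) -> np.ndarray:
    """First-PC loadings of the item correlation matrix.

    Items are standardized (correlation PCA), so a loading is the
    correlation between an item and the first component.  The sign is fixed
    so the loadings sum positive.
    """
    n, k = rows.shape
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} rows for {k} items, got {n}")
    sds = rows.std(axis=0, ddof=1)
    dead = [items[i] for i in range(k) if sds[i] == 0]
    if dead:
        raise ValueError(f"zero-variance item(s): {', '.join(dead)}")
    corr = np.corrcoef(rows, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(corr)
    lead = eigvecs[:, -1] * np.sqrt(max(eigvals[-1], 0.0))
    if lead.sum() < 0:
        lead = -lead
    return lead


def pca_loadings(responses: ResponseMatrix, scope: str = "general") -> LoadingVector:
    """Unidimensional PCA loadings, condition-general or condition-specific.

    ``scope="general"`` pools participant-condition rows from all
    conditions (within-condition centered, so condition mean shifts do not
    masquerade as a common factor); a condition label restricts to that
    condition's rows.
    """
    if scope == "general":
        rows = responses.pooled(within_condition_center=True)
        tag = "condition-general"
    else:
        rows = responses.condition(scope)
        tag = f"condition-specific:{scope}"
    loadings = _first_component_loadings(rows, responses.items)
    return LoadingVector(loadings=loadings, items=tuple(responses.items), scope=tag)


def tucker_congruence(x: LoadingVector | np.ndarray, y: LoadingVector | np.ndarray) -> float:
    """Tucker's congruence coefficient phi in [-1, 1].

    Invariant under positive rescaling of either vector; sign flips with
    the sign of the rescaling.
    """
    xv = np.asarray(x.loadings if isinstance(x, LoadingVector) else x, dtype=float)
    yv = np.asarray(y.loadings if isinstance(y, LoadingVector) else y, dtype=float)
    if xv.shape != yv.shape or xv.size < 2:
        raise ValueError("vectors must have equal length >= 2")
    nx = np.sqrt((xv**2).sum())
    ny = np.sqrt((yv**2).sum())
    if nx == 0 or ny == 0:
        raise ValueError("congruence is undefined for an all-zero vector")
    return float((xv * yv).sum() / (nx * ny))


def weighted_sum_score(
    responses: ResponseMatrix, loadings: LoadingVector | np.ndarray
) -> pd.DataFrame:
    """Weighted sum score per (participant, condition).

    ``score = sum_j lambda_j * response_j`` on the raw 0-100 values; unit
    loadings reduce to the plain item sum.
    """
    lv = np.asarray(loadings.loadings if isinstance(loadings, LoadingVector) else loadings,
                    dtype=float)
    if lv.size != len(responses.items):
        raise ValueError(
            f"loading length {lv.size} does not match item count {len(responses.items)}"
        )
    scores = np.einsum("pic,i->pc", responses.values, lv)
    return pd.DataFrame(scores, index=responses.participants,
                        columns=responses.conditions)


@dataclass(frozen=True)
class InvarianceReport:
    """Per-condition congruence between condition-general and
    condition-specific loadings (report-only unless a benchmark is set)."""

    general: LoadingVector
    specific: dict[str, LoadingVector]
    congruence: dict[str, float]
    benchmark: Optional[float] = None

    @property
    def min_condition(self) -> str:
        return min(self.congruence, key=self.congruence.get)

    @property
    def passed(self) -> Optional[bool]:
        if self.benchmark is None:
            return None
        return all(v >= self.benchmark for v in self.congruence.values())

    def summary(self) -> pd.DataFrame:
        rows = [
            {
                "condition": cond,
                "congruence": phi,
                "fair": phi >= CONGRUENCE_FAIR,
                "good": phi >= CONGRUENCE_GOOD,
            }
            for cond, phi in self.congruence.items()
        ]
        return pd.DataFrame(rows)


def invariance_check(
    responses: ResponseMatrix, benchmark: Optional[float] = None
) -> InvarianceReport:
    """Measurement-invariance check for the condition-general loadings.

    Computes phi between the pooled loadings and each condition's specific
    loadings.  With a single condition the two solutions coincide and phi
    is 1 by construction.
    """
    general = pca_loadings(responses, scope="general")
    specific: dict[str, LoadingVector] = {}
    congruence: dict[str, float] = {}
    for cond in responses.conditions:
        spec = pca_loadings(responses, scope=cond)
        specific[cond] = spec
        congruence[cond] = tucker_congruence(general, spec)
    return InvarianceReport(
        general=general, specific=specific, congruence=congruence, benchmark=benchmark
    )


def synth_responses(
    n_participants: int = 24,
    loadings: np.ndarray | None = None,
    condition_means: dict[str, float] | None = None,
    noise_sd: float = 10.0,
    seed: int = 0,
    items: Sequence[str] | None = None,
    latent_sd: float = 1.0,
) -> ResponseMatrix:
    """Generate one-factor questionnaire responses.

    ``response_ijc = clamp(mu_c + lambda_j * eta_ic + eps_ijc, 0, 100)``
    with ``eta_ic ~ N(0, latent_sd)`` and ``eps_ijc ~ N(0, noise_sd)``,
    all independent; deterministic per seed.  Defaults emulate a 4-item VAS
    questionnaire over the four study conditions with the qualitative mean
    ordering B < P < E <= PE.
    """
    if n_participants < 3:
        raise ValueError("need at least 3 participants")
    lv = DEFAULT_LOADINGS if loadings is None else np.asarray(loadings, dtype=float)
    means = DEFAULT_CONDITION_MEANS if condition_means is None else condition_means
    conditions = [c for c in CONDITIONS if c in means]
    if items is None:
        items = [f"item{j + 1}" for j in range(lv.size)]
    rng = np.random.default_rng(seed)
    n_i, n_c = lv.size, len(conditions)
    eta = latent_sd * rng.standard_normal((n_participants, n_c))
    eps = noise_sd * rng.standard_normal((n_participants, n_i, n_c))
    mu = np.array([means[c] for c in conditions])
    raw = mu[None, None, :] + lv[None, :, None] * eta[:, None, :] + eps
    values = np.clip(raw, 0.0, 100.0)
    return ResponseMatrix(values=values, items=list(items), conditions=conditions)
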