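"""Synthetic aged-care cohort generator.

Emulates the statistical shape the partial-GA method assumes: a latent
frailty trait ``z`` per resident drives a panel of binary health deficits
(``deficit_j ~ Bernoulli(logistic(a_j z + b_j))``, conditionally independent
given ``z``) and, more weakly, a block of ordinal administrative features
(noisy discretised transforms of ``z``).  A small number of derived low-cost
features are deterministic combinations of administrative features and also
act as deficits.  The binary frailty label is the deficit-accumulation index
over the declared deficit panel thresholded strictly at 0.21, so a model
given the whole panel can recover the label exactly while the
administrative block alone carries partial signal.

Default shape mirrors a residential-care cohort of 592 records with 32
clean administrative features, two additional administrative scales with
heavy missingness (36% and 42%, exercising the missingness filter), 3
derived low-cost deficits, and 32 stochastic high-cost deficits.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .data import FeatureSchema, FeatureSpec, FeatureTable
from .efi import EFIConfig, efi_scores
from .expressions import evaluate_expression

_DERIVED_PATTERNS = (
    "({a} >= {ta}) and ({b} >= {tb})",
    "max({a} >= {ta}, {b} >= {tb})",
    "({a} + {b}) >= {t}",
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters; defaults are the package's reference cohort.

    ``deficit_loadings``/``deficit_intercepts`` apply to the stochastic
    deficits only (``n_deficits - n_derived`` of them); the derived deficits
    are deterministic functions of administrative features.  With
    ``target_prevalence`` set, a common intercept shift is found by
    bisection until the observed frail fraction is within 0.02 of target.
    ``efi_panel`` overrides the deficit panel used for the label (default:
    all stochastic + derived deficits).
    """

    n_records: int = 592
    n_deficits: int = 35
    n_admin: int = 32
    n_derived: int = 3
    deficit_loadings: tuple[float, ...] | None = None
    deficit_intercepts: tuple[float, ...] | None = None
    admin_signal: float = 0.55
    admin_levels: tuple[int, ...] = (3, 4, 5)
    n_high_missing_admin: int = 2
    high_missing_rates: tuple[float, ...] = (0.36, 0.42)
    missingness_rates: Mapping[str, float] | None = None
    target_prevalence: float | None = 0.55
    efi_threshold: float = 0.21
    efi_panel: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_derived > self.n_deficits:
            raise ValueError("n_derived cannot exceed n_deficits")
        if self.n_derived > 0 and self.n_admin < 2:
            raise ValueError("derived features need at least 2 administrative features")
        n_stochastic = self.n_deficits - self.n_derived
        for name in ("deficit_loadings", "deficit_intercepts"):
            vec = getattr(self, name)
            if vec is not None:
                object.__setattr__(self, name, tuple(float(v) for v in vec))
                if len(vec) != n_stochastic:
                    raise ValueError(
                        f"{name} must have length n_deficits - n_derived = {n_stochastic}"
                    )
        if not 0.0 <= self.admin_signal < 1.0:
            raise ValueError("admin_signal must lie in [0, 1)")
        if len(self.high_missing_rates) < self.n_high_missing_admin:
            raise ValueError("need a missingness rate per high-missing admin feature")
        for r in self.high_missing_rates:
            if not 0.0 <= r < 1.0:
                raise ValueError("missingness rates must lie in [0, 1)")
        if self.target_prevalence is not None and not 0.0 < self.target_prevalence < 1.0:
            raise ValueError("target_prevalence must lie in (0, 1)")

    @property
    def n_stochastic_deficits(self) -> int:
        return self.n_deficits - self.n_derived


@dataclass
class SyntheticCohort:
    """Generated table + schema + ground truth for recovery tests."""

    table: FeatureTable
    schema: FeatureSchema
    truth: dict


def _default_loadings(n: int) -> np.ndarray:
    if n == 1:
        return np.array([1.3])
    return np.linspace(0.8, 1.8, n)


def _default_intercepts(n: int) -> np.ndarray:
    if n == 1:
        return np.array([-1.0])
    return np.linspace(-1.6, -0.4, n)


def _admin_names(config: SyntheticConfig) -> list[str]:
    clean = [f"adm_{i + 1:02d}" for i in range(config.n_admin)]
    extra = [f"adm_{config.n_admin + i + 1:02d}" for i in range(config.n_high_missing_admin)]
    return clean + extra


def _derived_definitions(config: SyntheticConfig, levels: Mapping[str, int]) -> dict[str, str]:
    """Binary combination rules over pairs of administrative features."""
    names = [f"adm_{i + 1:02d}" for i in range(config.n_admin)]
    definitions = {}
    for d in range(config.n_derived):
        a = names[(2 * d) % len(names)]
        b = names[(2 * d + 1) % len(names)]
        ta, tb = max(levels[a] // 2, 1), max(levels[b] // 2, 1)
        pattern = _DERIVED_PATTERNS[d % len(_DERIVED_PATTERNS)]
        definitions[f"der_{d + 1}"] = pattern.format(a=a, b=b, ta=ta, tb=tb, t=ta + tb)
    return definitions


def generate(config: SyntheticConfig) -> SyntheticCohort:
    """Draw one cohort; bit-identical for identical configs.

    Raises if a requested target prevalence cannot be reached by shifting
    the deficit intercepts within a bounded search.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_records
    z = rng.standard_normal(n)

    # administrative block: ordinal discretisations of admin_signal·z + noise
    admin_names = _admin_names(config)
    levels = {
        name: config.admin_levels[i % len(config.admin_levels)]
        for i, name in enumerate(admin_names)
    }
    s = config.admin_signal
    admin = {}
    for name in admin_names:
        latent = s * z + np.sqrt(1.0 - s * s) * rng.standard_normal(n)
        k = levels[name]
        # equal-probability bins of the standard normal
        cuts = np.quantile(np.sort(latent), np.linspace(0, 1, k + 1)[1:-1])
        admin[name] = np.digitize(latent, cuts).astype(float)
    frame = pd.DataFrame(admin, index=[f"r{i + 1:04d}" for i in range(n)])

    # derived low-cost deficits: deterministic combinations of admin features
    definitions = _derived_definitions(config, levels)
    for name, expr in definitions.items():
        frame[name] = evaluate_expression(expr, frame)

    # stochastic high-cost deficits from the latent trait
    n_stoch = config.n_stochastic_deficits
    a = np.asarray(
        config.deficit_loadings
        if config.deficit_loadings is not None
        else _default_loadings(n_stoch)
    )
    b = np.asarray(
        config.deficit_intercepts
        if config.deficit_intercepts is not None
        else _default_intercepts(n_stoch)
    )
    u = rng.random((n, n_stoch))
    deficit_names = [f"def_{j + 1:02d}" for j in range(n_stoch)]
    panel = tuple(config.efi_panel) if config.efi_panel is not None else tuple(
        deficit_names + list(definitions)
    )
    efi = EFIConfig(deficit_names=panel, threshold=config.efi_threshold)

    def realise(delta: float) -> pd.DataFrame:
        probs = 1.0 / (1.0 + np.exp(-(z[:, None] * a[None, :] + b[None, :] + delta)))
        out = frame.copy()
        for j, name in enumerate(deficit_names):
            out[name] = (u[:, j] < probs[:, j]).astype(float)
        return out

    def prevalence(values: pd.DataFrame) -> float:
        return float(efi_scores(values, efi)["frail"].mean())

    delta = 0.0
    if config.target_prevalence is not None:
        lo, hi = -6.0, 6.0
        target = config.target_prevalence
        if prevalence(realise(lo)) > target + 0.02 or prevalence(realise(hi)) < target - 0.02:
            raise ValueError(
                f"target prevalence {target} unattainable by intercept shift in [{lo}, {hi}]"
            )
        for _ in range(80):
            delta = 0.5 * (lo + hi)
            p = prevalence(realise(delta))
            if abs(p - target) <= 0.02:
                break
            if p < target:
                lo = delta
            else:
                hi = delta
        else:
            raise ValueError(
                f"target prevalence {target} not reached within 0.02 after bounded search"
            )
    values = realise(delta)

    scores = efi_scores(values, efi)
    labels = scores["frail"].astype(int)
    labels.name = "frail"

    # MCAR missingness: the two heavy-missingness admin scales by default,
    # plus any user-configured per-feature rates
    rates = {
        name: config.high_missing_rates[i]
        for i, name in enumerate(admin_names[config.n_admin :])
    }
    if config.missingness_rates:
        rates.update(config.missingness_rates)
    masked = values.copy()
    for name, rate in rates.items():
        if rate > 0:
            mask = rng.random(n) < rate
            masked.loc[mask, name] = np.nan

    specs: dict[str, FeatureSpec] = {}
    for name in admin_names:
        specs[name] = FeatureSpec(
            name=name,
            cost_class="low",
            domain=f"ordinal({levels[name]})",
            source="administrative",
        )
    for name, expr in definitions.items():
        specs[name] = FeatureSpec(
            name=name, cost_class="low", domain="binary", source="derived", definition=expr
        )
    for name in deficit_names:
        specs[name] = FeatureSpec(name=name, cost_class="high", domain="binary", source="deficit")
    schema = FeatureSchema(features=specs, efi=efi)

    loadings_by_name = {name: float(a[j]) for j, name in enumerate(deficit_names)}
    ranking = sorted(deficit_names, key=lambda m: -abs(loadings_by_name[m]))
    truth = {
        "latent_trait": z.tolist(),
        "loadings": loadings_by_name,
        "intercept_shift": delta,
        "ranking": ranking,
        "labels": labels.tolist(),
        "prevalence": float(labels.mean()),
    }
    table = FeatureTable(values=masked, label=labels)
    return SyntheticCohort(table=table, schema=schema, truth=truth)


def planted_subset_cohort(
    n_informative: int, config: SyntheticConfig | None = None
) -> SyntheticCohort:
    """Cohort with a known informative deficit subset for recovery tests.

    Exactly ``n_informative`` stochastic deficits receive loading ``+2``;
    the rest get loading 0 (pure Bernoulli noise, independent of the latent
    trait).  The eFI panel is restricted to the informative deficits, so
    noise deficits are label-independent by construction and
    ``truth["informative"]`` is the planted ground truth.
    """
    if config is None:
        config = SyntheticConfig(
            n_records=600,
            n_deficits=32,
            n_admin=0,
            n_derived=0,
            n_high_missing_admin=0,
            target_prevalence=0.5,
        )
    n_stoch = config.n_stochastic_deficits
    if not 1 <= n_informative <= n_stoch:
        raise ValueError(f"n_informative must lie in [1, {n_stoch}]")
    rng = np.random.default_rng(config.seed + 104729)  # independent placement stream
    positions = np.sort(rng.choice(n_stoch, size=n_informative, replace=False))
    loadings = np.zeros(n_stoch)
    loadings[positions] = 2.0
    intercepts = np.full(n_stoch, np.log(0.3 / 0.7))  # noise prevalence ≈ 0.3
    intercepts[positions] = 0.0
    informative = tuple(f"def_{j + 1:02d}" for j in positions)
    cohort = generate(
        replace(
            config,
            deficit_loadings=tuple(loadings),
            deficit_intercepts=tuple(intercepts),
            efi_panel=informative,
        )
    )
    cohort.truth["informative"] = list(informative)
    cohort.truth["ranking"] = list(informative) + [
        n for n in cohort.truth["ranking"] if n not in informative
    ]
    return cohort
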