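"""Two-level generators for stimulus-generalization gradient data.

The generating model is a random-intercept / random-slope hierarchical
linear model.  Each subject ``i`` observes every stimulus ``j`` on an
ordered dimension ``d`` (CS+ at ``d = 0``, CS- at the far end) and
produces a response

    y_ij = b0_i + b1_i * d_j + eps_ij,        eps_ij ~ N(0, sigma2_eps)

with subject-level (level-2) models

    b0_i = gamma00 + gamma01 * u_i + U0_i
    b1_i = gamma10 + gamma11 * u_i + U1_i

where ``u_i`` is a continuous subject covariate (an individual-differences
score) and ``(U0_i, U1_i)`` is bivariate normal with covariance
``[[tau00, tau01], [tau01, tau11]]``, independent of the level-1 errors.
``gamma11`` is the cross-level interaction: how strongly the gradient
slope depends on the trait ``u``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "SubjectEffects",
    "default_config",
    "simulate_dataset",
    "simulate_worked_example",
]

#: Columns of the canonical long-format gradient dataset.
DATASET_COLUMNS = ("subject", "d", "u", "y")


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterization of the two-level gradient generator.

    Parameters
    ----------
    n_subjects
        Number of level-2 units (subjects); must be >= 2.
    n_stimuli
        Number of stimuli per subject (length of ``d_values``).
    gamma00, gamma10
        Fixed intercept and fixed slope of the stimulus dimension ``d``.
    gamma01, gamma11
        Effect of the subject covariate ``u`` on the intercept and on the
        slope (the cross-level interaction).
    tau00, tau11, tau01
        Random-intercept variance, random-slope variance and their
        covariance; ``[[tau00, tau01], [tau01, tau11]]`` must be positive
        semi-definite.
    sigma2_eps
        Level-1 residual variance (> 0).
    u_spec
        Distribution of ``u_i``: ``("uniform", low, high)``,
        ``("normal", mean, sd)`` or ``("constant", value)``.
    d_values
        Ordered stimulus codes; defaults to ``0..n_stimuli-1``.
    seed
        Seed used when no explicit generator is passed to
        :func:`simulate_dataset`.
    """

    n_subjects: int
    n_stimuli: int = 10
    gamma00: float = 0.0
    gamma10: float = 0.0
    gamma01: float = 0.0
    gamma11: float = 0.0
    tau00: float = 0.0
    tau11: float = 0.0
    tau01: float = 0.0
    sigma2_eps: float = 1.0
    u_spec: tuple = ("uniform", 0.0, 10.0)
    d_values: tuple = field(default=None)  # type: ignore[assignment]
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2 (no between-subject "
                             "analysis is possible with a single subject)")
        if self.n_stimuli < 1:
            raise ValueError("n_stimuli must be positive")
        if self.d_values is None:
            object.__setattr__(self, "d_values",
                               tuple(float(j) for j in range(self.n_stimuli)))
        else:
            object.__setattr__(self, "d_values",
                               tuple(float(v) for v in self.d_values))
        if len(self.d_values) != self.n_stimuli:
            raise ValueError("n_stimuli must equal len(d_values)")
        if self.sigma2_eps <= 0:
            raise ValueError("sigma2_eps must be > 0")
        if self.tau00 < 0 or self.tau11 < 0:
            raise ValueError("random-effect variances must be >= 0")
        # PSD check for the 2x2 random-effects covariance
        det = self.tau00 * self.tau11 - self.tau01 ** 2
        if det < -1e-12 * max(1.0, self.tau00 * self.tau11):
            raise ValueError(
                "random-effects covariance [[tau00, tau01], [tau01, tau11]] "
                "is not positive semi-definite")
        kind = self.u_spec[0]
        if kind not in ("uniform", "normal", "constant"):
            raise ValueError(f"unknown u_spec kind {kind!r}")

    @property
    def re_cov(self) -> np.ndarray:
        """The 2x2 random-effects covariance matrix."""
        return np.array([[self.tau00, self.tau01],
                         [self.tau01, self.tau11]])

    def to_dict(self) -> dict:
        return {
            "n_subjects": self.n_subjects,
            "n_stimuli": self.n_stimuli,
            "gamma00": self.gamma00,
            "gamma10": self.gamma10,
            "gamma01": self.gamma01,
            "gamma11": self.gamma11,
            "tau00": self.tau00,
            "tau11": self.tau11,
            "tau01": self.tau01,
            "sigma2_eps": self.sigma2_eps,
            "u_spec": list(self.u_spec),
            "d_values": list(self.d_values),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "u_spec" in d:
            d["u_spec"] = tuple(d["u_spec"])
        if d.get("d_values") is not None:
            d["d_values"] = tuple(d["d_values"])
        return cls(**d)


@dataclass(frozen=True)
class SubjectEffects:
    """Realized random effects and subject-level coefficients of one subject."""

    u0: float  #: random intercept deviation U0_i
    u1: float  #: random slope deviation U1_i
    b0: float  #: subject intercept  b0_i = gamma00 + gamma01*u_i + U0_i
    b1: float  #: subject slope      b1_i = gamma10 + gamma11*u_i + U1_i


def default_config(n_subjects: int = 20, gamma11: float = 0.0,
                   seed: int = 0) -> SimulationConfig:
    """Generator parameters of the reference Monte-Carlo study.

    The defaults describe a 10-stimulus US-expectancy gradient task: a
    high response to the CS+ at ``d = 0`` declining along the dimension,
    substantial between-subject spread in both intercept and slope (the
    random slope is what breaks sphericity in the implied 10x10 response
    covariance), and a 0-10 individual-differences score ``u`` that
    lowers the CS+ response and, through ``gamma11``, flattens the
    gradient.
    """
    return SimulationConfig(
        n_subjects=n_subjects,
        n_stimuli=10,
        gamma00=7.91871,
        gamma10=-0.58322,
        gamma01=-0.37375,
        gamma11=gamma11,
        tau00=2.5324,
        tau11=0.1345,
        tau01=-0.46,
        sigma2_eps=2.4348,
        u_spec=("uniform", 0.0, 10.0),
        seed=seed,
    )


def _draw_u(spec: tuple, n: int, rng: np.random.Generator) -> np.ndarray:
    kind = spec[0]
    if kind == "uniform":
        return rng.uniform(spec[1], spec[2], size=n)
    if kind == "normal":
        return rng.normal(spec[1], spec[2], size=n)
    if kind == "constant":
        return np.full(n, float(spec[1]))
    raise ValueError(f"unknown u_spec kind {kind!r}")


def draw_subject_effects(config: SimulationConfig, u: np.ndarray,
                         rng: np.random.Generator) -> list[SubjectEffects]:
    """Draw the level-2 random effects for subjects with covariate ``u``."""
    n = len(u)
    cov = config.re_cov
    # Cholesky-like square root that tolerates semi-definite covariances
    w, v = np.linalg.eigh(cov)
    root = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    z = rng.standard_normal((n, 2)) @ root.T
    out = []
    for i in range(n):
        u0, u1 = z[i]
        out.append(SubjectEffects(
            u0=u0, u1=u1,
            b0=config.gamma00 + config.gamma01 * u[i] + u0,
            b1=config.gamma10 + config.gamma11 * u[i] + u1,
        ))
    return out


def simulate_dataset(config: SimulationConfig,
                     rng: np.random.Generator | int | None = None
                     ) -> pd.DataFrame:
    """Simulate one balanced long-format gradient dataset.

    Returns a DataFrame with columns ``subject, d, u, y`` containing
    ``n_subjects * n_stimuli`` rows, subject-major, stimuli in ``d_values``
    order.  The same ``config`` and seed always yield an identical frame.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    elif isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    n, k = config.n_subjects, config.n_stimuli
    d = np.asarray(config.d_values, dtype=float)

    u = _draw_u(config.u_spec, n, rng)
    cov = config.re_cov
    w, v = np.linalg.eigh(cov)
    root = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    re = rng.standard_normal((n, 2)) @ root.T        # (n, 2): U0, U1
    b0 = config.gamma00 + config.gamma01 * u + re[:, 0]
    b1 = config.gamma10 + config.gamma11 * u + re[:, 1]
    eps = rng.normal(0.0, math.sqrt(config.sigma2_eps), size=(n, k))
    y = b0[:, None] + b1[:, None] * d[None, :] + eps

    return pd.DataFrame({
        "subject": np.repeat(np.arange(n), k),
        "d": np.tile(d, n),
        "u": np.repeat(u, k),
        "y": y.ravel(),
    })


#: Default fixed quadratic coefficients of the worked-example emulator:
#: (gamma00, gamma10, gamma20) -- intercept, linear and quadratic terms in d.
WORKED_EXAMPLE_FIXED = (9.3, -0.45, -0.045)
#: Moderator coefficients (gamma01 on the intercept, gamma11 on the slope).
WORKED_EXAMPLE_MODERATOR = (-0.30, 0.08)
#: Random-effect (co)variances (tau00, tau01, tau11) and residual variance.
WORKED_EXAMPLE_VC = (2.3, -0.25, 0.12, 2.3)


def simulate_worked_example(n_subjects: int = 52,
                            rng: np.random.Generator | int | None = None,
                            coefficients: tuple[float, float, float] | None = None,
                            noiseless: bool = False,
                            clip: bool = True) -> pd.DataFrame:
    """Emulate a Cyberball-style social-exclusion generalization study.

    This is a synthetic stand-in for an (unavailable) US-expectancy
    experiment: 52 subjects rate, on a 0-10 scale, how strongly they
    expect to be excluded by each of 10 player profiles morphed between
    an excluder (CS+, ``d = 0``) and a fair player (CS-, ``d = 9``).
    The mean gradient is a decreasing quadratic in ``d``; a 0-10
    individual-differences score ``u`` lowers the CS+ response and
    flattens the gradient.  Responses are clipped to the rating scale
    unless ``clip=False`` (useful when the unbounded generating model
    itself is under study, e.g. for parameter recovery).

    With ``noiseless=True`` all random effects, the moderator and the
    residual noise are switched off, so every subject's gradient equals
    the fixed quadratic exactly.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(0 if rng is None else int(rng))
    g00, g10, g20 = coefficients if coefficients is not None else WORKED_EXAMPLE_FIXED
    g01, g11 = WORKED_EXAMPLE_MODERATOR
    t00, t01, t11, s2 = WORKED_EXAMPLE_VC
    if noiseless:
        g01 = g11 = t00 = t01 = t11 = s2 = 0.0

    n, k = n_subjects, 10
    d = np.arange(k, dtype=float)
    u = rng.uniform(0.0, 10.0, size=n)
    cov = np.array([[t00, t01], [t01, t11]])
    w, v = np.linalg.eigh(cov)
    root = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    re = rng.standard_normal((n, 2)) @ root.T
    b0 = g00 + g01 * u + re[:, 0]
    b1 = g10 + g11 * u + re[:, 1]
    eps = (rng.normal(0.0, math.sqrt(s2), size=(n, k)) if s2 > 0
           else np.zeros((n, k)))
    y = b0[:, None] + b1[:, None] * d[None, :] + g20 * d[None, :] ** 2 + eps
    if clip:
        y = np.clip(y, 0.0, 10.0)

    return pd.DataFrame({
        "subject": np.repeat(np.arange(n), k),
        "d": np.tile(d, n),
        "u": np.repeat(u, k),
        "y": y.ravel(),
    })


def with_params(config: SimulationConfig, **kwargs) -> SimulationConfig:
    """Return a copy of ``config`` with the given fields replaced."""
    return replace(config, **kwargs)
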