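"""Quencher-penetration kinetics of a fluorophore-labelled membrane behind a
porous cell wall.

The model: a wall of thickness ``h`` separates a bath containing a quencher at
constant concentration ``q_b`` from the plasma membrane (thickness
``h_m << h``).  The quencher diffuses through the wall — treated as a
homogeneous porous medium with porosity ``phi``, tortuosity ``eta(phi)`` and
pore-level diffusion coefficient ``C*D`` — and accumulates in the membrane,
whose concentration ``q_m(t)`` obeys

    dq_m/dt = (q_b - q_m) / T,      T = h_m * h / D_e,
    D_e     = C * phi * D / eta(phi),

so ``q_m(t) = q_b * (1 - exp(-t/T))``.  The observed relative fluorescence
follows Stern–Volmer quenching, ``I = 1 / (1 + K q_m)``.  Fitting ``I(t)``
yields ``K`` and the characteristic time ``T`` per sample; under the Bruggeman
tortuosity law ``eta = phi**-0.5`` the ratio of two samples' porosities is
recoverable from their characteristic times alone:

    phi_alt / phi_ref = (T_ref / T_alt) ** (2/3).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares


class DomainError(ValueError):
    """A physical quantity is outside its admissible domain."""


class ConfigurationError(ValueError):
    """An identifier or option combination is not recognised."""


class DegenerateSeriesError(ValueError):
    """The data carry no quenching signal (constant intensities)."""


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

def bruggeman_tortuosity(phi: float) -> float:
    """Bruggeman tortuosity ``eta = phi**-1/2`` for porosity ``phi`` in (0, 1].

    Assumes a homogeneous, isotropic porous structure of particles much
    smaller than the sample.
    """
    phi = np.asarray(phi, dtype=float)
    if np.any(phi <= 0) or np.any(phi > 1):
        raise DomainError(f"porosity must lie in (0, 1], got {phi}")
    return phi ** -0.5


#: Registry of tortuosity laws eta(phi); pluggable, only Bruggeman ships.
TORTUOSITY_RULES: dict[str, Callable[[float], float]] = {
    "bruggeman": bruggeman_tortuosity,
}


@dataclass(frozen=True)
class WallGeometry:
    """Wall/membrane geometry. SI units (m, m²)."""

    h: float        # wall thickness, m (~280e-9 for leaf epidermis)
    h_m: float      # membrane thickness, m (~10e-9)
    A: float = 1.0  # sample area, m²; cancels in all intensity predictions

    def __post_init__(self) -> None:
        if self.h <= 0 or self.h_m <= 0 or self.A <= 0:
            raise DomainError("h, h_m and A must be positive")
        if self.h_m >= self.h:
            raise DomainError("membrane must be thinner than the wall (h_m < h)")


@dataclass(frozen=True)
class PorousMedium:
    """Porous-wall transport parameters.

    ``C`` attenuates the bath diffusion coefficient inside a pore
    (``D_p = C*D``, with C << 1 physically); ``tortuosity_rule`` names an
    entry of :data:`TORTUOSITY_RULES`.
    """

    phi: float
    C: float
    D: float
    tortuosity_rule: str = "bruggeman"

    def __post_init__(self) -> None:
        if not 0 < self.phi <= 1:
            raise DomainError(f"porosity must lie in (0, 1], got {self.phi}")
        if not 0 < self.C <= 1:
            raise DomainError(f"attenuation factor C must lie in (0, 1], got {self.C}")
        if self.D <= 0:
            raise DomainError("bath diffusion coefficient D must be positive")
        if self.tortuosity_rule not in TORTUOSITY_RULES:
            raise ConfigurationError(
                f"unknown tortuosity rule {self.tortuosity_rule!r}; "
                f"known: {sorted(TORTUOSITY_RULES)}"
            )

    @property
    def tortuosity(self) -> float:
        return TORTUOSITY_RULES[self.tortuosity_rule](self.phi)


@dataclass(frozen=True)
class QuencherBath:
    """Bath quencher concentration, mol m⁻³; constant over the experiment."""

    q_b: float

    def __post_init__(self) -> None:
        if self.q_b <= 0:
            raise DomainError("bath concentration q_b must be positive")


@dataclass(frozen=True)
class SternVolmerParams:
    """Stern–Volmer quencher constant ``K = k_q * tau_0`` (m³ mol⁻¹)."""

    K: float
    k_q: float | None = None   # quencher rate coefficient, m³ mol⁻¹ s⁻¹
    tau_0: float | None = None  # unquenched decay timescale, s

    def __post_init__(self) -> None:
        if self.K <= 0:
            raise DomainError("quencher constant K must be positive")
        if self.k_q is not None and self.tau_0 is not None:
            if not np.isclose(self.K, self.k_q * self.tau_0, rtol=1e-9):
                raise DomainError("K must equal k_q * tau_0 when both are given")


@dataclass
class FluorescenceSeries:
    """Relative fluorescence ``I = F/F0`` against time for one sample/ROI.

    Times are stored in seconds; use :meth:`from_minutes` for tables recorded
    in minutes.
    """

    times: np.ndarray
    intensities: np.ndarray
    label: str = ""
    replicate_id: str | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.shape != self.intensities.shape:
            raise DomainError("times and intensities must have equal length")
        if np.any(self.times < 0):
            raise DomainError("times must be non-negative")
        if np.any(np.diff(self.times) <= 0):
            raise DomainError("times must be strictly increasing")
        if np.any(self.intensities <= 0):
            raise DomainError("intensities must be positive")

    @classmethod
    def from_minutes(
        cls,
        times_min: Sequence[float],
        intensities: Sequence[float],
        label: str = "",
        replicate_id: str | None = None,
    ) -> "FluorescenceSeries":
        return cls(np.asarray(times_min, dtype=float) * 60.0,
                   np.asarray(intensities, dtype=float), label, replicate_id)


@dataclass
class QuenchFit:
    """Result of fitting ``I(t) = 1/(1 + K q_b (1 - exp(-t/T)))``."""

    K_hat: float
    T_hat: float
    se_K: float
    se_T: float
    rss: float
    n_obs: int
    converged: bool
    label: str = ""


# --------------------------------------------------------------------------
# Forward model
# --------------------------------------------------------------------------

def effective_diffusion(medium: PorousMedium) -> float:
    """Effective wall diffusion coefficient ``D_e = C * phi * D / eta(phi)``."""
    return medium.C * medium.phi * medium.D / medium.tortuosity


def characteristic_time(geom: WallGeometry, medium: PorousMedium) -> float:
    """Membrane-filling timescale ``T = h_m * h / D_e``, seconds."""
    return geom.h_m * geom.h / effective_diffusion(medium)


def membrane_concentration(t, bath: QuencherBath, T: float):
    """Membrane quencher concentration ``q_m(t) = q_b (1 - exp(-t/T))``."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise DomainError("time must be non-negative")
    if T <= 0:
        raise DomainError("characteristic time T must be positive")
    return bath.q_b * (1.0 - np.exp(-t / T))


def diffusional_flux(D_e: float, q_b: float, q_m, h: float):
    """Fickian flux ``J_D = -D_e (q_b - q_m) / h`` (mol m⁻² s⁻¹).

    Negative while the membrane is below bath concentration: the quencher
    flows into the wall (against +z).
    """
    if h <= 0:
        raise DomainError("wall thickness h must be positive")
    return -D_e * (q_b - np.asarray(q_m, dtype=float)) / h


def integrate_ode(bath: QuencherBath, T: float, t_grid: Sequence[float]) -> np.ndarray:
    """Numerically integrate ``dq_m/dt = (q_b - q_m)/T`` from ``q_m(0) = 0``.

    Serves as the independent oracle for :func:`membrane_concentration`.
    High-order integration (DOP853) at tight tolerances so agreement with the
    closed form can be checked to ~1e-8 relative.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid[0] != 0 or np.any(np.diff(t_grid) <= 0):
        raise DomainError("t_grid must increase strictly from 0")
    if T <= 0:
        raise DomainError("characteristic time T must be positive")
    sol = solve_ivp(
        lambda _t, q: (bath.q_b - q) / T,
        (0.0, float(t_grid[-1])),
        y0=[0.0],
        t_eval=t_grid,
        method="DOP853",
        rtol=1e-12,
        atol=bath.q_b * 1e-14,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return sol.y[0]


def stern_volmer_intensity(q_m, params: SternVolmerParams):
    """Relative intensity ``I = 1 / (1 + K q_m)``, in (0, 1]."""
    q_m = np.asarray(q_m, dtype=float)
    if np.any(q_m < 0):
        raise DomainError("quencher concentration must be non-negative")
    return 1.0 / (1.0 + params.K * q_m)


def forward_decay(
    times,
    params: SternVolmerParams,
    T: float,
    bath: QuencherBath,
    label: str = "",
) -> FluorescenceSeries:
    """Predicted fluorescence decay ``I(t) = 1/(1 + K q_b (1 - exp(-t/T)))``.

    Monotone non-increasing from ``I(0) = 1`` to the plateau
    ``1/(1 + K q_b)``.
    """
    q_m = membrane_concentration(times, bath, T)
    return FluorescenceSeries(np.asarray(times, dtype=float),
                              stern_volmer_intensity(q_m, params), label=label)


# --------------------------------------------------------------------------
# Fitting
# --------------------------------------------------------------------------

def _decay_model(t, K, T, q_b):
    return 1.0 / (1.0 + K * q_b * (1.0 - np.exp(-t / T)))


def fit_decay(
    series: FluorescenceSeries | Sequence[FluorescenceSeries],
    bath: QuencherBath,
    init: tuple[float, float] | None = None,
) -> QuenchFit:
    """Fit ``(K, T)`` to one series, or jointly to replicate series.

    Ordinary least squares on the intensities (noise is observed on I, not on
    the linearised transform), with positivity enforced through bounds.  The
    t=0 observation participates in the fit; I(0) is not pinned to 1.
    Several series are pooled with shared ``(K, T)``.

    Parameters
    ----------
    series : one FluorescenceSeries or a sequence of replicates
    bath : QuencherBath
    init : optional ``(K0, T0)`` starting values; defaults to the plateau
        estimate ``K0 = (1/I_last - 1)/q_b`` and ``T0 =`` half the window.

    Returns
    -------
    QuenchFit with estimates, standard errors from the Gauss–Newton
    approximation of the covariance, RSS and a convergence flag.
    """
    if isinstance(series, FluorescenceSeries):
        group = [series]
    else:
        group = list(series)
        if not group:
            raise DomainError("no series to fit")
    t = np.concatenate([s.times for s in group])
    y = np.concatenate([s.intensities for s in group])
    label = group[0].label
    if len(np.unique(t)) < 3:
        raise DomainError("need at least 3 distinct time points")
    if np.ptp(y) == 0:
        raise DegenerateSeriesError(
            "intensities are constant: no quenching signal to fit"
        )

    if init is None:
        i_last = float(np.mean(y[t == t.max()]))
        K0 = max((1.0 / min(i_last, 1.0 - 1e-9) - 1.0) / bath.q_b, 1e-12)
        T0 = 0.5 * float(t.max())
    else:
        K0, T0 = init
    # log-parameterisation keeps K, T positive and evens out the scales
    theta0 = np.log([K0, T0])

    def resid(theta):
        K, T = np.exp(theta)
        return _decay_model(t, K, T, bath.q_b) - y

    res = least_squares(resid, theta0, method="lm", xtol=1e-10, ftol=1e-12,
                        gtol=1e-12, max_nfev=10_000)
    K_hat, T_hat = np.exp(res.x)
    rss = float(2.0 * res.cost)
    n = t.size
    dof = max(n - 2, 1)
    # covariance in log-space via Gauss-Newton, delta-method back to (K, T)
    try:
        JTJ = res.jac.T @ res.jac
        cov_log = np.linalg.inv(JTJ) * rss / dof
        se_K = float(np.sqrt(max(cov_log[0, 0], 0.0)) * K_hat)
        se_T = float(np.sqrt(max(cov_log[1, 1], 0.0)) * T_hat)
    except np.linalg.LinAlgError:
        se_K = se_T = float("nan")
    return QuenchFit(float(K_hat), float(T_hat), se_K, se_T, rss, n,
                     bool(res.success), label=label)


def mean_series(replicates: Sequence[FluorescenceSeries]) -> FluorescenceSeries:
    """Average replicate ROIs sharing a common time grid into one series."""
    reps = list(replicates)
    if not reps:
        raise DomainError("no replicates to average")
    t0 = reps[0].times
    for s in reps[1:]:
        if s.times.shape != t0.shape or not np.allclose(s.times, t0):
            raise DomainError("replicates must share one time grid to be averaged")
    I = np.mean([s.intensities for s in reps], axis=0)
    return FluorescenceSeries(t0.copy(), I, label=reps[0].label)


def fit_label_groups(
    collection: dict[str, list[FluorescenceSeries]],
    bath: QuencherBath,
    mode: str = "mean",
    init: tuple[float, float] | None = None,
) -> dict[str, QuenchFit]:
    """Fit each genotype/label independently.

    ``mode="mean"`` (default) fits the ROI-averaged curve, matching how mean
    F/F0 curves are presented; ``mode="pooled"`` fits all replicate points
    jointly with shared (K, T).  K is estimated per label; see
    :func:`porosity_ratio_from_times` for the cross-label inference.
    """
    if mode not in ("mean", "pooled"):
        raise ConfigurationError(f"unknown fit mode {mode!r}")
    out = {}
    for label, reps in collection.items():
        target = mean_series(reps) if mode == "mean" else reps
        fit = fit_decay(target, bath, init=init)
        fit.label = label
        out[label] = fit
    return out


def fit_shared_K(
    collection: dict[str, list[FluorescenceSeries]],
    bath: QuencherBath,
    mode: str = "mean",
) -> dict[str, QuenchFit]:
    """Joint fit of all labels with one shared K and a per-label T.

    The quencher constant K characterises the quencher-fluorophore pair,
    not the sample, so when the labels differ only in wall structure a
    single K is the physically natural model.  Tying K across labels also
    removes the strong K-T anti-correlation of the independent fits, which
    tightens every characteristic-time estimate — the quantity the porosity
    ratio is built from.
    """
    if mode not in ("mean", "pooled"):
        raise ConfigurationError(f"unknown fit mode {mode!r}")
    labels = list(collection)
    if not labels:
        raise DomainError("no series to fit")
    data = []
    for label in labels:
        reps = collection[label]
        group = [mean_series(reps)] if mode == "mean" else reps
        t = np.concatenate([s.times for s in group])
        y = np.concatenate([s.intensities for s in group])
        if len(np.unique(t)) < 3:
            raise DomainError(f"label {label!r}: need ≥3 distinct time points")
        if np.ptp(y) == 0:
            raise DegenerateSeriesError(f"label {label!r}: constant intensities")
        data.append((t, y))

    i_last = float(np.mean([y[t == t.max()].mean() for t, y in data]))
    K0 = max((1.0 / min(i_last, 1.0 - 1e-9) - 1.0) / bath.q_b, 1e-12)
    T0s = [0.5 * float(t.max()) for t, _ in data]
    theta0 = np.log([K0] + T0s)

    def resid(theta):
        K = np.exp(theta[0])
        Ts = np.exp(theta[1:])
        return np.concatenate([
            _decay_model(t, K, Ts[i], bath.q_b) - y
            for i, (t, y) in enumerate(data)
        ])

    res = least_squares(resid, theta0, method="lm", xtol=1e-10, ftol=1e-12,
                        gtol=1e-12, max_nfev=10_000)
    K_hat = float(np.exp(res.x[0]))
    T_hats = np.exp(res.x[1:])
    rss = float(2.0 * res.cost)
    n = sum(t.size for t, _ in data)
    dof = max(n - len(res.x), 1)
    try:
        cov_log = np.linalg.inv(res.jac.T @ res.jac) * rss / dof
        ses = np.sqrt(np.clip(np.diag(cov_log), 0.0, None))
    except np.linalg.LinAlgError:
        ses = np.full(len(res.x), np.nan)
    out = {}
    for i, label in enumerate(labels):
        out[label] = QuenchFit(
            K_hat, float(T_hats[i]), float(ses[0] * K_hat),
            float(ses[i + 1] * T_hats[i]), rss, data[i][0].size,
            bool(res.success), label=label,
        )
    return out


def porosity_ratio_from_times(T_ref: float, T_alt: float) -> float:
    """Porosity ratio ``phi_alt / phi_ref = (T_ref / T_alt)**(2/3)``.

    Follows from T ∝ eta(phi)/phi with Bruggeman eta = phi**-1/2, assuming
    the two samples differ only in porosity (and hence tortuosity).  Scale
    invariant in the pair of times.
    """
    if T_ref <= 0 or T_alt <= 0:
        raise DomainError("characteristic times must be positive")
    return (T_ref / T_alt) ** (2.0 / 3.0)
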