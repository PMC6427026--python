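"""Worm-like-chain mechanics of fibril traces.

A fibril imaged on a surface is digitised as a 2D polyline
(:class:`FibrilTrace`). For a surface-equilibrated 2D worm-like chain with
persistence length ``P`` the mean squared end-to-end distance of a chain of
contour length ``L`` is

    <D^2> = 4 P L * [ 1 - (2P/L) * (1 - exp(-L / 2P)) ]

Fitting this relation to per-fibril ``(L, D^2)`` pairs yields ``P``, which
converts to the bending rigidity ``B = P * kB * T``.

:class:`WormLikeChainModel` follows the statsmodels Model/Results pattern:
construct from data, call :meth:`~WormLikeChainModel.fit`, inspect the
returned :class:`WLCResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .exceptions import FitError, ParameterError
from .scales import BOLTZMANN_JK

#: Documented cap of the persistence-length fit (um). A fit pinned here
#: indicates effectively straight fibrils (rigid limit).
P_MAX_UM = 1.0e4
P_MIN_UM = 1.0e-6


@dataclass
class FibrilTrace:
    """Ordered 2D polyline of one fibril backbone, coordinates in nm."""

    vertices: np.ndarray  # (N, 2), nm
    fibril_id: str = "fibril"

    def __post_init__(self):
        v = np.asarray(self.vertices, float)
        if v.ndim != 2 or v.shape[1] != 2 or len(v) < 2:
            raise ParameterError("a trace needs >= 2 two-dimensional vertices")
        seg = np.linalg.norm(np.diff(v, axis=0), axis=1)
        if np.any(seg == 0):
            raise ParameterError("consecutive trace vertices must be distinct")
        self.vertices = v

    def measure(self) -> tuple[float, float]:
        """(contour length, end-to-end distance) in nm."""
        seg = np.linalg.norm(np.diff(self.vertices, axis=0), axis=1)
        contour = float(seg.sum())
        end_to_end = float(np.linalg.norm(self.vertices[-1] - self.vertices[0]))
        return contour, end_to_end


def measure_trace(trace: FibrilTrace) -> tuple[float, float]:
    """Contour length L and end-to-end distance D of a trace (same units as
    the vertices; D <= L always)."""
    return trace.measure()


def wlc_expected_sq_end_to_end(contour_length, persistence_length):
    """Mean squared end-to-end distance of a 2D worm-like chain.

    Parameters are in consistent length units (conventionally um); the
    return value is in those units squared. Vectorised in ``contour_length``.
    """
    L = np.asarray(contour_length, float)
    P = float(persistence_length)
    if np.any(L <= 0) or P <= 0:
        raise ParameterError("contour length and persistence length must be > 0")
    x = L / (2.0 * P)
    # bracket = 1 - (1/x)(1 - e^-x), written with expm1 for small x
    bracket = 1.0 + np.expm1(-x) / x
    out = 4.0 * P * L * bracket
    return float(out) if np.isscalar(contour_length) else out


def bending_rigidity(persistence_length_um: float, temperature_k: float) -> float:
    """Bending rigidity B = P * kB * T in N m^2 (P given in um)."""
    if persistence_length_um < 0:
        raise ParameterError("persistence length must be >= 0")
    if temperature_k <= 0:
        raise ParameterError("temperature must be > 0")
    return persistence_length_um * 1e-6 * BOLTZMANN_JK * temperature_k


class WormLikeChainModel:
    """Persistence-length model for an ensemble of traced fibrils.

    Parameters
    ----------
    contour_lengths_um, end_to_end_um
        Per-fibril contour length and end-to-end distance, um. One
        observation per fibril; no binning.
    temperature_k
        Temperature for the rigidity conversion (default 300 K).
    """

    def __init__(self, contour_lengths_um, end_to_end_um, temperature_k: float = 300.0):
        L = np.asarray(contour_lengths_um, float)
        D = np.asarray(end_to_end_um, float)
        if L.shape != D.shape or L.ndim != 1:
            raise ParameterError("contour and end-to-end arrays must be equal-length 1D")
        if len(L) < 2:
            raise ParameterError("need >= 2 fibrils to fit a persistence length")
        if np.any(L <= 0) or np.any(D <= 0):
            raise ParameterError("lengths must be positive")
        if np.any(D > L * (1 + 1e-9)):
            raise ParameterError("end-to-end distance cannot exceed contour length")
        self.contour_um = L
        self.end_to_end_um = D
        self.temperature_k = float(temperature_k)

    @classmethod
    def from_traces(cls, traces, temperature_k: float = 300.0) -> "WormLikeChainModel":
        """Build from :class:`FibrilTrace` objects (nm) -> model in um."""
        pairs = np.array([t.measure() for t in traces], float) / 1000.0
        return cls(pairs[:, 0], pairs[:, 1], temperature_k)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, temperature_k: float = 300.0) -> "WormLikeChainModel":
        """Build from a DataFrame with columns ``contour_um`` and ``end_to_end_um``."""
        return cls(df["contour_um"].to_numpy(), df["end_to_end_um"].to_numpy(),
                   temperature_k)

    # ------------------------------------------------------------------

    def _fit_once(self, L, D2, p0):
        popt, pcov = curve_fit(wlc_expected_sq_end_to_end, L, D2, p0=[p0],
                               bounds=([P_MIN_UM], [P_MAX_UM]), maxfev=10000)
        return float(popt[0]), float(np.sqrt(pcov[0, 0]))

    def fit(self, n_bootstrap: int = 1000, seed: int = 42) -> "WLCResults":
        """Unweighted least-squares fit of D^2 vs L.

        The fit standard error comes from the curvature of the objective;
        ``n_bootstrap`` seeded case resamples of the fibrils give a second,
        distribution-free uncertainty. Set ``n_bootstrap=0`` to skip.
        """
        L, D = self.contour_um, self.end_to_end_um
        D2 = D ** 2
        p0 = float(np.clip(D2.max() / (4.0 * L.max()), 0.01, 100.0))
        try:
            p_hat, p_se = self._fit_once(L, D2, p0)
        except RuntimeError as exc:  # pragma: no cover - curve_fit rarely fails with bounds
            raise FitError(f"persistence-length fit did not converge: {exc}") from exc
        at_cap = p_hat >= 0.99 * P_MAX_UM
        if at_cap:
            warnings.warn("fit pinned at the rigid-limit cap "
                          f"({P_MAX_UM:g} um): fibrils are effectively straight",
                          stacklevel=2)
        boot = np.array([])
        if n_bootstrap > 0:
            rng = np.random.default_rng(seed)
            samples = []
            n = len(L)
            for _ in range(n_bootstrap):
                idx = rng.integers(0, n, n)
                try:
                    pb, _ = self._fit_once(L[idx], D2[idx], p0)
                except RuntimeError:
                    continue
                samples.append(pb)
            boot = np.asarray(samples)
        return WLCResults(model=self, persistence_length_um=p_hat,
                          se_um=p_se, bootstrap_samples=boot,
                          at_upper_bound=at_cap, seed=seed)


@dataclass
class WLCResults:
    """Persistence-length fit results; also the serialisable WLC fit record."""

    model: WormLikeChainModel
    persistence_length_um: float
    se_um: float                      # curve-fit standard error
    bootstrap_samples: np.ndarray = field(default_factory=lambda: np.array([]))
    at_upper_bound: bool = False
    seed: int = 42
    boltzmann_jk: float = BOLTZMANN_JK

    @property
    def n_fibrils(self) -> int:
        return len(self.model.contour_um)

    @property
    def temperature_k(self) -> float:
        return self.model.temperature_k

    @property
    def bootstrap_se_um(self) -> float:
        if len(self.bootstrap_samples) < 2:
            return float("nan")
        return float(np.std(self.bootstrap_samples, ddof=1))

    @property
    def bending_rigidity_nm2(self) -> float:
        """B = P kB T, N m^2."""
        return bending_rigidity(self.persistence_length_um, self.temperature_k)

    @property
    def bending_rigidity_se_nm2(self) -> float:
        se = self.bootstrap_se_um if np.isfinite(self.bootstrap_se_um) else self.se_um
        return bending_rigidity(se, self.temperature_k)

    def predict(self, contour_lengths_um):
        """Model D^2 (um^2) at the fitted persistence length."""
        return wlc_expected_sq_end_to_end(contour_lengths_um, self.persistence_length_um)

    def conf_int(self, alpha: float = 0.05) -> tuple[float, float]:
        """Bootstrap percentile interval (falls back to +/-1.96 SE)."""
        if len(self.bootstrap_samples) >= 20:
            lo, hi = np.quantile(self.bootstrap_samples, [alpha / 2, 1 - alpha / 2])
            return float(lo), float(hi)
        z = 1.959963984540054
        return (self.persistence_length_um - z * self.se_um,
                self.persistence_length_um + z * self.se_um)

    def to_dict(self) -> dict:
        return {
            "P_um": self.persistence_length_um,
            "P_se_um": self.se_um,
            "P_bootstrap_se_um": self.bootstrap_se_um,
            "B_Nm2": self.bending_rigidity_nm2,
            "B_se_Nm2": self.bending_rigidity_se_nm2,
            "temperature_K": self.temperature_k,
            "n": self.n_fibrils,
            "at_upper_bound": self.at_upper_bound,
        }

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            "Worm-like-chain persistence length fit",
            "=" * 46,
            f"n fibrils            {self.n_fibrils:>12d}",
            f"temperature          {self.temperature_k:>12.1f} K",
            f"persistence length P {self.persistence_length_um:>12.3f} um",
            f"  fit SE             {self.se_um:>12.3f} um",
            f"  bootstrap SE       {self.bootstrap_se_um:>12.3f} um"
            f"  (n={len(self.bootstrap_samples)})",
            f"  95% CI             [{ci[0]:.3f}, {ci[1]:.3f}] um",
            f"bending rigidity B   {self.bending_rigidity_nm2:>12.3e} N m^2",
            f"  SE                 {self.bending_rigidity_se_nm2:>12.3e} N m^2",
        ]
        if self.at_upper_bound:
            lines.append(f"WARNING: fit pinned at the rigid-limit cap ({P_MAX_UM:g} um)")
        return "\n".join(lines)

    def plot_fit(self, ax=None):
        """Scatter of D^2 vs L with the fitted curve."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        L = self.model.contour_um
        ax.plot(L, self.model.end_to_end_um ** 2, "o", ms=4, alpha=0.6,
                label="fibrils")
        grid = np.linspace(L.min(), L.max(), 200)
        ax.plot(grid, self.predict(grid), "-",
                label=f"WLC fit, P = {self.persistence_length_um:.2f} um")
        ax.set_xlabel("contour length L (um)")
        ax.set_ylabel(r"squared end-to-end distance $D^2$ (um$^2$)")
        ax.legend()
        return ax


def fit_persistence_length(observations, temperature_k: float = 300.0,
                           n_bootstrap: int = 1000, seed: int = 42) -> WLCResults:
    """Functional wrapper: fit P from an iterable of (L, D) pairs in um."""
    obs = np.asarray(list(observations), float)
    if obs.ndim != 2 or obs.shape[1] != 2:
        raise ParameterError("observations must be (L, D) pairs")
    model = WormLikeChainModel(obs[:, 0], obs[:, 1], temperature_k)
    return model.fit(n_bootstrap=n_bootstrap, seed=seed)
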