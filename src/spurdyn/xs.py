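"""Electron-water interaction channels: construction, evaluation, sampling.

Inelastic channels (ionisation and electronic excitation) are backed by a
Drude-oscillator parameterisation of the liquid-water energy-loss function
Im(-1/eps(0, w')) and evaluated through Ashley's optical-data formula for the
inverse mean free path,

    1/lambda(E) = 1/(2 pi E) * Int_0^{E/2} Im(-1/eps(0,w')) L(w'/E) dw',
    L(a) = (1-a) ln(4/a) - 7/4 a + a^{3/2} - 33/32 a^2 .

The expression is evaluated in Hartree atomic units; the Hartree factors cancel
in the dimensionless integrand, leaving a single division by the Bohr radius to
express the result per cm.  Cross sections follow from sigma = 1/(lambda N).

Molecular channels (rotation, intra-/inter-molecular vibration) are tabulated
sigma(E) curves with log-log interpolation.  Elastic scattering is Moliere's
screened cross section, with its momentum-transfer companion used for the
thermal energy exchange with the 300 K bath.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .constants import (
    BOHR_CM,
    ETA_C_LOW,
    ETA_C_SWITCH_EV,
    M0C2,
    R_ELECTRON_CM,
    WATER_DENSITY_CM3,
    WATER_EFFECTIVE_Z,
)

CHANNEL_KINDS = (
    "ionisation",
    "electronic_excitation",
    "rotation",
    "intra_vibration",
    "inter_vibration",
    "elastic",
)
ELF_KINDS = ("ionisation", "electronic_excitation")
MOLECULAR_KINDS = ("rotation", "intra_vibration", "inter_vibration")


class UnknownChannelError(KeyError):
    """Raised when a channel identifier is not present in the bundle."""


@dataclass(frozen=True)
class DrudeTerm:
    """One Drude oscillator of the energy-loss function.

    The term contributes  A * g * w / ((w0^2 - w^2)^2 + (g w)^2)  to
    Im(-1/eps(0, w)); it vanishes at w = 0 and is non-negative for w >= 0.

    Parameters
    ----------
    channel_id : str
        Inelastic channel this oscillator strength is assigned to.
    amplitude : float
        Oscillator amplitude A, eV^2.
    center : float
        Transition (resonance) energy w0, eV.
    width : float
        Damping energy g, eV.
    """

    channel_id: str
    amplitude: float
    center: float
    width: float

    def __post_init__(self) -> None:
        if not (self.amplitude > 0 and self.center > 0 and self.width > 0):
            raise ValueError(
                f"Drude term {self.channel_id!r}: amplitude, center and width "
                "must be strictly positive"
            )

    def __call__(self, omega: np.ndarray | float) -> np.ndarray | float:
        w = np.asarray(omega, dtype=float)
        val = (
            self.amplitude
            * self.width
            * w
            / ((self.center**2 - w**2) ** 2 + (self.width * w) ** 2)
        )
        return val if val.ndim else float(val)


@dataclass(frozen=True)
class ChannelSpec:
    """Identity and bookkeeping data of one interaction channel."""

    channel_id: str
    kind: str
    transition_energy: float
    spawns_electron: bool = False

    def __post_init__(self) -> None:
        if self.kind not in CHANNEL_KINDS:
            raise ValueError(f"unknown channel kind {self.kind!r}")
        if self.kind != "elastic" and not self.transition_energy > 0:
            raise ValueError(
                f"channel {self.channel_id!r}: transition_energy must be > 0"
            )
        if self.spawns_electron and self.kind != "ionisation":
            raise ValueError("only ionisation channels spawn electrons")


@dataclass(frozen=True)
class TabulatedChannel:
    """Columnar sigma(E) table with log-log interpolation.

    Inside the grid the cross section is interpolated log-log; outside it is
    clamped to the edge values.  Zero table entries are handled by flooring at
    a tiny positive value during interpolation and snapping back to zero.
    """

    channel_spec: ChannelSpec
    energy_grid: np.ndarray
    sigma_values: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.energy_grid, dtype=float)
        s = np.asarray(self.sigma_values, dtype=float)
        if e.ndim != 1 or e.shape != s.shape:
            raise ValueError("energy grid and sigma values must be 1-D and equal length")
        if not np.all(np.diff(e) > 0):
            raise ValueError("energy grid must be strictly increasing")
        if np.any(s < 0):
            raise ValueError("cross sections must be non-negative")
        object.__setattr__(self, "energy_grid", e)
        object.__setattr__(self, "sigma_values", s)

    def __call__(self, energy: np.ndarray | float) -> np.ndarray | float:
        e = np.asarray(energy, dtype=float)
        scalar = e.ndim == 0
        e = np.atleast_1d(e)
        floor = 1e-300
        logs = np.log(np.maximum(self.sigma_values, floor))
        out = np.exp(np.interp(np.log(np.maximum(e, 1e-300)), np.log(self.energy_grid), logs))
        out[out < 1e-250] = 0.0
        # exact values at grid nodes
        idx = np.searchsorted(self.energy_grid, e)
        on_node = (idx < len(self.energy_grid)) & np.isclose(
            e, self.energy_grid[np.minimum(idx, len(self.energy_grid) - 1)]
        )
        out[on_node] = self.sigma_values[np.minimum(idx, len(self.energy_grid) - 1)][on_node]
        return float(out[0]) if scalar else out


@dataclass
class CrossSectionBundle:
    """All interaction channels of the medium, with evaluable sigma(E).

    The bundle owns the Drude terms of the energy-loss function, the channel
    list, the tabulated molecular channels, and the medium constants used by
    the Moliere elastic machinery.
    """

    drude_terms: list[DrudeTerm]
    channels: list[ChannelSpec]
    tables: list[TabulatedChannel] = field(default_factory=list)
    molecular_density: float = WATER_DENSITY_CM3
    effective_Z: float = WATER_EFFECTIVE_Z
    eta_c_low: float = ETA_C_LOW
    screening_form: str = "tau_tau_plus_1"
    disabled_channels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        ids = [c.channel_id for c in self.channels]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate channel identifiers")
        by_id = {c.channel_id: c for c in self.channels}
        n_elastic = sum(1 for c in self.channels if c.kind == "elastic")
        if n_elastic != 1:
            raise ValueError("bundle must contain exactly one elastic channel")
        for t in self.drude_terms:
            spec = by_id.get(t.channel_id)
            if spec is None or spec.kind not in ELF_KINDS:
                raise ValueError(
                    f"Drude term {t.channel_id!r} is not assigned to an "
                    "ionisation or electronic-excitation channel"
                )
        for t in self.tables:
            if t.channel_spec.channel_id not in by_id:
                raise ValueError(
                    f"table channel {t.channel_spec.channel_id!r} missing from channel list"
                )
        self._by_id = by_id
        self._tables_by_id = {t.channel_spec.channel_id: t for t in self.tables}

    # -- lookup helpers -------------------------------------------------
    def channel(self, channel_id: str) -> ChannelSpec:
        try:
            return self._by_id[channel_id]
        except KeyError:
            raise UnknownChannelError(
                f"unknown channel {channel_id!r}; known: {sorted(self._by_id)}"
            ) from None

    def table(self, channel_id: str) -> TabulatedChannel:
        self.channel(channel_id)
        try:
            return self._tables_by_id[channel_id]
        except KeyError:
            raise UnknownChannelError(
                f"channel {channel_id!r} has no tabulated cross section"
            ) from None

    def terms_for(self, channel_id: str | None) -> list[DrudeTerm]:
        if channel_id is None:
            return [t for t in self.drude_terms if t.channel_id not in self.disabled_channels]
        self.channel(channel_id)
        return [t for t in self.drude_terms if t.channel_id == channel_id]

    @property
    def elastic_channel(self) -> ChannelSpec:
        return next(c for c in self.channels if c.kind == "elastic")

    def elf_channel_ids(self) -> list[str]:
        return [
            c.channel_id
            for c in self.channels
            if c.kind in ELF_KINDS and c.channel_id not in self.disabled_channels
        ]

    def active_channels(self) -> list[ChannelSpec]:
        return [c for c in self.channels if c.channel_id not in self.disabled_channels]

    def is_elf_channel(self, channel_id: str) -> bool:
        return self.channel(channel_id).kind in ELF_KINDS

    # -- thin evaluation wrappers ---------------------------------------
    def elf(self, omega_prime, channel_filter: str | None = None):
        return elf_value(self, omega_prime, channel_filter)

    def sigma(self, energy, channel_id: str, thresholded: bool | None = None):
        return sigma_channel(self, energy, channel_id, thresholded=thresholded)


# ---------------------------------------------------------------------------
# energy-loss function and Ashley inverse mean free path
# ---------------------------------------------------------------------------

def elf_value(
    bundle: CrossSectionBundle,
    omega_prime: np.ndarray | float,
    channel_filter: str | None = None,
) -> np.ndarray | float:
    """Evaluate Im(-1/eps(0, w')) as the sum of the bundle's Drude terms.

    With ``channel_filter`` the sum is restricted to the oscillators assigned
    to that channel.  Non-negative everywhere; exactly zero at w' = 0.
    """
    w = np.asarray(omega_prime, dtype=float)
    if np.any(w < 0):
        raise ValueError("omega_prime must be >= 0")
    terms = bundle.terms_for(channel_filter)
    out = np.zeros_like(w, dtype=float)
    for t in terms:
        out = out + t(w)
    return float(out) if out.ndim == 0 else out


def ashley_L(a: np.ndarray | float) -> np.ndarray | float:
    """Exchange-corrected transfer kernel L(a) on the domain (0, 1/2]."""
    arr = np.asarray(a, dtype=float)
    if np.any(arr <= 0) or np.any(arr > 0.5):
        raise ValueError("ashley_L domain is 0 < a <= 1/2")
    out = (1 - arr) * np.log(4.0 / arr) - 1.75 * arr + arr**1.5 - (33.0 / 32.0) * arr**2
    return float(out) if out.ndim == 0 else out


def _channel_threshold_applies(spec: ChannelSpec, thresholded: bool | None) -> bool:
    if thresholded is None:
        return spec.kind == "ionisation"
    return thresholded


def ashley_imfp(
    bundle: CrossSectionBundle,
    energy: float,
    channel_id: str,
    *,
    thresholded: bool | None = None,
    n_grid: int = 3000,
) -> float:
    """Inverse mean free path of one ELF-backed channel, per cm.

    Numerically integrates the Ashley formula with a dense trapezoid over
    (0, E/2].  ``thresholded=None`` applies the transition-energy threshold to
    ionisation channels only (the reporting convention of the bundled cross
    sections); ``True`` forces it for electronic excitations as well (the
    transport convention), ``False`` disables it.
    """
    spec = bundle.channel(channel_id)
    if spec.kind not in ELF_KINDS:
        raise ValueError(
            f"channel {channel_id!r} ({spec.kind}) is not ELF-backed; "
            "evaluate its tabulated cross section instead"
        )
    if not energy > 0:
        raise ValueError("energy must be positive")
    if _channel_threshold_applies(spec, thresholded) and energy < spec.transition_energy:
        return 0.0
    upper = energy / 2.0
    w = np.linspace(upper * 1e-6, upper, n_grid)
    integrand = elf_value(bundle, w, channel_id) * ashley_L(w / energy)
    integral = float(np.trapezoid(integrand, w))
    return max(integral / (2.0 * np.pi * energy) / BOHR_CM, 0.0)


def sigma_from_imfp(imfp: float, density: float) -> float:
    """Convert an inverse mean free path (per cm) to a cross section (cm^2)."""
    if not density > 0:
        raise ValueError("density must be positive")
    if imfp < 0:
        raise ValueError("inverse mean free path must be non-negative")
    return imfp / density


# ---------------------------------------------------------------------------
# Moliere elastic scattering
# ---------------------------------------------------------------------------

def _beta_sq(energy: float | np.ndarray) -> np.ndarray | float:
    tau = np.asarray(energy, dtype=float) / M0C2
    return 1.0 - 1.0 / (1.0 + tau) ** 2


def moliere_screening(energy: np.ndarray | float, bundle: CrossSectionBundle) -> np.ndarray | float:
    """Screening parameter eta of the Moliere cross section."""
    e = np.asarray(energy, dtype=float)
    if np.any(e <= 0):
        raise ValueError("energy must be positive")
    tau = e / M0C2
    z = bundle.effective_Z
    beta2 = _beta_sq(e)
    eta_c = np.where(
        e < ETA_C_SWITCH_EV,
        bundle.eta_c_low,
        1.13 + 3.76 * (z / (137.0 * np.sqrt(beta2))) ** 2,
    )
    if bundle.screening_form == "tau_tau_plus_1":
        denom = tau * (tau + 1.0)
    elif bundle.screening_form == "tau_tau_plus_2":
        denom = tau * (tau + 2.0)
    else:
        raise ValueError(f"unknown screening_form {bundle.screening_form!r}")
    eta = eta_c * 1.7e-5 * z ** (2.0 / 3.0) / denom
    return float(eta) if eta.ndim == 0 else eta


def _moliere_prefactor(energy: np.ndarray | float, bundle: CrossSectionBundle):
    """C = pi Z (Z+1) r_e^2 (1-beta^2)/beta^4, cm^2."""
    z = bundle.effective_Z
    beta2 = _beta_sq(energy)
    return np.pi * z * (z + 1.0) * R_ELECTRON_CM**2 * (1.0 - beta2) / beta2**2


def moliere_dcs(
    energy: float, theta: np.ndarray | float, bundle: CrossSectionBundle
) -> np.ndarray | float:
    """Moliere differential elastic cross section q(theta), cm^2."""
    th = np.asarray(theta, dtype=float)
    if np.any(th < 0) or np.any(th > np.pi):
        raise ValueError("theta must lie in [0, pi]")
    eta = moliere_screening(energy, bundle)
    c = _moliere_prefactor(energy, bundle)
    q = c / (1.0 - np.cos(th) + 2.0 * eta) ** 2
    return float(q) if q.ndim == 0 else q


def sigma_elastic(energy: np.ndarray | float, bundle: CrossSectionBundle) -> np.ndarray | float:
    """Integral Moliere elastic cross section, cm^2 (no low-energy cutoff)."""
    eta = moliere_screening(energy, bundle)
    c = _moliere_prefactor(energy, bundle)
    out = c / (eta * (eta + 1.0))
    return float(out) if np.ndim(out) == 0 else out


def sigma_momentum_transfer(
    energy: np.ndarray | float, bundle: CrossSectionBundle
) -> np.ndarray | float:
    """Momentum-transfer cross section 2 Int (1-cos t) q(t) sin t dt, cm^2.

    Evaluated by the closed form 2C[ln(1 + 1/eta) - 1/(1 + eta)].
    """
    eta = moliere_screening(energy, bundle)
    c = _moliere_prefactor(energy, bundle)
    out = 2.0 * c * (np.log1p(1.0 / eta) - 1.0 / (1.0 + eta))
    return float(out) if np.ndim(out) == 0 else out


# ---------------------------------------------------------------------------
# per-channel cross sections and samplers
# ---------------------------------------------------------------------------

def sigma_channel(
    bundle: CrossSectionBundle,
    energy: float,
    channel_id: str,
    *,
    thresholded: bool | None = None,
) -> float:
    """sigma(E) of any channel in cm^2, dispatching on its kind."""
    spec = bundle.channel(channel_id)
    if channel_id in bundle.disabled_channels:
        return 0.0
    if spec.kind == "elastic":
        return float(sigma_elastic(energy, bundle))
    if spec.kind in ELF_KINDS:
        imfp = ashley_imfp(bundle, energy, channel_id, thresholded=thresholded)
        return sigma_from_imfp(imfp, bundle.molecular_density)
    return float(bundle.table(channel_id)(energy))


def sample_channel(
    bundle: CrossSectionBundle,
    energy: float,
    u: np.ndarray | float,
    *,
    thresholded: bool | None = True,
) -> str | np.ndarray:
    """Sample a channel identifier with probability sigma_i / sigma_total.

    The transport threshold convention (``thresholded=True``) is the default:
    below every inelastic transition energy only the elastic and molecular
    channels can be drawn.
    """
    ids = [c.channel_id for c in bundle.active_channels()]
    sigmas = np.array(
        [sigma_channel(bundle, energy, cid, thresholded=thresholded) for cid in ids]
    )
    total = sigmas.sum()
    if not total > 0:
        raise ValueError(f"total cross section vanishes at E = {energy} eV")
    cdf = np.cumsum(sigmas) / total
    uu = np.asarray(u, dtype=float)
    idx = np.searchsorted(cdf, uu, side="right")
    idx = np.minimum(idx, len(ids) - 1)
    if uu.ndim == 0:
        return ids[int(idx)]
    return np.array(ids, dtype=object)[idx]


def energy_transfer_density(
    bundle: CrossSectionBundle,
    energy: float,
    channel_id: str,
    *,
    weight_L: bool = True,
    n_grid: int = 4096,
) -> tuple[np.ndarray, np.ndarray]:
    """Unnormalised transfer density ELF_ch(w') [* L(w'/E)] on (0, E/2]."""
    spec = bundle.channel(channel_id)
    if spec.kind not in ELF_KINDS:
        raise ValueError(f"channel {channel_id!r} is not ELF-backed")
    upper = energy / 2.0
    w = np.linspace(upper * 1e-6, upper, n_grid)
    dens = np.asarray(elf_value(bundle, w, channel_id), dtype=float)
    if weight_L:
        dens = dens * ashley_L(w / energy)
    return w, dens


def sample_energy_transfer(
    bundle: CrossSectionBundle,
    energy: float,
    channel_id: str,
    u: np.ndarray | float,
    *,
    weight_L: bool = True,
) -> np.ndarray | float:
    """Inverse-CDF draw of the energy transfer w' for an ELF-backed channel.

    The sampling density is the Ashley integrand ELF_ch(w') L(w'/E) on
    (0, E/2] (the L factor can be dropped), so sampling is consistent with the
    channel's inverse mean free path.  Always <= E/2.
    """
    w, dens = energy_transfer_density(bundle, energy, channel_id, weight_L=weight_L)
    cum = np.concatenate([[0.0], np.cumsum((dens[1:] + dens[:-1]) * 0.5 * np.diff(w))])
    if not cum[-1] > 0:
        raise ValueError(
            f"channel {channel_id!r} has empty transfer support at E = {energy} eV"
        )
    cdf = cum / cum[-1]
    out = np.interp(np.asarray(u, dtype=float), cdf, w)
    out = np.minimum(out, energy / 2.0)
    return float(out) if np.ndim(u) == 0 else out


def sample_elastic_angle(
    energy: float, bundle: CrossSectionBundle, u: np.ndarray | float
) -> np.ndarray | float:
    """Inverse-CDF draw of the Moliere polar scattering angle, radians."""
    eta = moliere_screening(energy, bundle)
    uu = np.asarray(u, dtype=float)
    inv = 1.0 / (2.0 * eta) - uu * (1.0 / (2.0 * eta) - 1.0 / (2.0 + 2.0 * eta))
    t = 1.0 / inv  # = 1 - cos(theta) + 2 eta
    cos_theta = np.clip(1.0 + 2.0 * eta - t, -1.0, 1.0)
    out = np.arccos(cos_theta)
    return float(out) if np.ndim(u) == 0 else out


def total_imfp_per_nm(
    bundle: CrossSectionBundle, energy: float, *, thresholded: bool | None = True
) -> float:
    """Total inverse mean free path at E, in nm^-1 (transport convention)."""
    from .constants import CM2_TO_NM2

    n_nm3 = bundle.molecular_density * 1e-21
    total = sum(
        sigma_channel(bundle, energy, c.channel_id, thresholded=thresholded)
        for c in bundle.active_channels()
    )
    return total * CM2_TO_NM2 * n_nm3


def export_sigma_table(
    bundle: CrossSectionBundle,
    energies: Sequence[float] | np.ndarray,
    channel_ids: Iterable[str] | None = None,
    *,
    thresholded: bool | None = None,
) -> dict[str, np.ndarray]:
    """Per-channel sigma(E) curves on a requested grid, for plotting/diffing."""
    energies = np.asarray(energies, dtype=float)
    ids = list(channel_ids) if channel_ids is not None else [
        c.channel_id for c in bundle.active_channels()
    ]
    out: dict[str, np.ndarray] = {"energy_eV": energies}
    for cid in ids:
        out[cid] = np.array(
            [sigma_channel(bundle, e, cid, thresholded=thresholded) for e in energies]
        )
    return out
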