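"""Ensemble reductions: radial distributions, collision maps, spur summaries.

The conventions follow the reference figures: terminal electron positions are
binned by the *relative distance to their own parent cation* into spherical
shells of width 0.1 nm ("calculation 1" = initial electrons only,
"calculation 2" = additional electrons, "calculation 3" = all); collision maps
bin ionisation + electronic-excitation event positions by distance from the
initial deposition site; the spur radius is the radius enclosing a configured
percentile (default 95%) of the *delocalised* (>= 1 nm) initial electrons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .transport import HistoryRecord, maxwell_energy_cdf

GROUPS = ("initial", "additional", "all")

#: sentinel returned when every electron relocalised and no radius is defined
UNDEFINED_RADIUS = float("nan")


@dataclass
class RadialHistogram:
    """Shell counts over own-parent distance (or origin distance for events)."""

    bin_width: float
    counts: dict[str, np.ndarray]
    n_trials: int

    def edges(self) -> np.ndarray:
        n = len(next(iter(self.counts.values())))
        return np.arange(n + 1) * self.bin_width

    def group(self, name: str) -> np.ndarray:
        if name not in self.counts:
            raise ValueError(f"unknown group {name!r}; known: {sorted(self.counts)}")
        return self.counts[name]


def _bin_distances(distances: np.ndarray, bin_width: float, n_bins: int) -> np.ndarray:
    idx = np.floor(np.asarray(distances, dtype=float) / bin_width).astype(int)
    idx = np.clip(idx, 0, n_bins - 1)
    return np.bincount(idx, minlength=n_bins).astype(float)


def radial_distribution(
    histories: Sequence[HistoryRecord],
    group: str = "all",
    *,
    bin_width: float = 0.1,
) -> RadialHistogram:
    """Bin terminal own-parent distances into Delta-r shells, per group."""
    if len(histories) == 0:
        raise ValueError("need at least one history")
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
    d_init = np.concatenate([h.terminal_distances("initial") for h in histories])
    d_add_list = [h.terminal_distances("additional") for h in histories]
    d_add = (
        np.concatenate([d for d in d_add_list])
        if d_add_list
        else np.array([])
    )
    dmax = max(d_init.max(initial=0.0), d_add.max(initial=0.0))
    n_bins = max(int(math.floor(dmax / bin_width)) + 1, 1)
    counts = {
        "initial": _bin_distances(d_init, bin_width, n_bins),
        "additional": _bin_distances(d_add, bin_width, n_bins)
        if d_add.size
        else np.zeros(n_bins),
    }
    counts["all"] = counts["initial"] + counts["additional"]
    return RadialHistogram(bin_width=bin_width, counts=counts, n_trials=len(histories))


def collision_map(
    histories: Sequence[HistoryRecord],
    *,
    bin_width: float = 0.1,
    kinds_prefixes: tuple[str, ...] = ("ion_", "exc_"),
    reference: str = "origin",
) -> RadialHistogram:
    """Per-trial-normalised shell counts of inelastic electronic events.

    Bins ionisation + electronic-excitation event positions by distance from
    the initial deposition site (the origin); ``reference='parent'`` is not
    implemented for events because the engine logs absolute positions — the
    per-parent view is the radial_distribution of the electrons themselves.
    """
    if len(histories) == 0:
        raise ValueError("need at least one history")
    if reference != "origin":
        raise ValueError("only the origin reference is supported for event maps")
    dists = []
    for h in histories:
        for ev in h.events:
            if any(ev.channel_id.startswith(p) for p in kinds_prefixes):
                dists.append(float(np.linalg.norm(ev.position)))
    if dists:
        arr = np.asarray(dists)
        n_bins = int(math.floor(arr.max() / bin_width)) + 1
        counts = _bin_distances(arr, bin_width, n_bins) / len(histories)
    else:
        counts = np.zeros(1)
    return RadialHistogram(
        bin_width=bin_width, counts={"events": counts}, n_trials=len(histories)
    )


def mean_event_number(
    histories: Sequence[HistoryRecord],
    kinds_prefixes: Iterable[str] = ("ion_", "exc_"),
) -> tuple[float, float]:
    """Mean (and standard error) of per-history counts of the given kinds."""
    prefixes = tuple(kinds_prefixes)
    if not prefixes:
        raise ValueError("kinds must not be empty")
    if len(histories) < 2:
        raise ValueError("need at least two histories for a standard error")
    per = np.array(
        [
            sum(
                n
                for cid, n in h.counts.items()
                if any(cid.startswith(p) for p in prefixes) and not cid.endswith("+gain")
            )
            for h in histories
        ],
        dtype=float,
    )
    return float(per.mean()), float(per.std(ddof=1) / math.sqrt(len(per)))


def spur_radius(
    histogram: RadialHistogram,
    percentile: float = 0.95,
    *,
    group: str = "initial",
    exclude_below: float = 1.0,
) -> float:
    """Radius enclosing ``percentile`` of the delocalised initial electrons.

    The relocalised component (< 1 nm) is excluded; the radius is linearly
    interpolated within the crossing bin.  Returns NaN (with a warning) when
    every electron relocalised.
    """
    if not 0 < percentile <= 1:
        raise ValueError("percentile must lie in (0, 1]")
    counts = histogram.group(group).astype(float).copy()
    edges = histogram.edges()
    cut = np.searchsorted(edges, exclude_below, side="left")
    counts[: min(cut, len(counts))] = 0.0
    total = counts.sum()
    if total <= 0:
        import warnings

        warnings.warn(
            "all electrons relocalised; spur radius undefined", stacklevel=2
        )
        return UNDEFINED_RADIUS
    cum = np.cumsum(counts) / total
    target = percentile
    i = int(np.searchsorted(cum, target, side="left"))
    i = min(i, len(counts) - 1)
    prev = cum[i - 1] if i > 0 else 0.0
    frac = (target - prev) / max(cum[i] - prev, 1e-300)
    return float(edges[i] + frac * histogram.bin_width)


def maxwellian_distance(
    kinetic_energies: np.ndarray | Sequence[float], temperature: float
) -> float:
    """Two-sided KS distance to the Maxwell-Boltzmann kinetic-energy CDF."""
    e = np.sort(np.asarray(kinetic_energies, dtype=float))
    if e.size < 50:
        raise ValueError("need at least 50 samples for a stable KS distance")
    cdf = np.asarray(maxwell_energy_cdf(e, temperature))
    n = e.size
    upper = np.max(np.arange(1, n + 1) / n - cdf)
    lower = np.max(cdf - np.arange(0, n) / n)
    return float(max(upper, lower))


@dataclass
class SpurSummary:
    """Per-deposition-energy summary of one ensemble."""

    deposition_energy: float
    n_trials: int
    spur_radius: float
    spur_radius_percentile: float
    spur_radius_sensitivity: dict[str, float]
    mean_event_number: float
    mean_event_number_se: float
    relocalised_fraction: float
    relocalised_fraction_se: float
    mean_additional_electrons: float
    maxwellian_ks: float
    temperature: float

    def as_dict(self) -> dict:
        return {
            "deposition_energy_eV": self.deposition_energy,
            "n_trials": self.n_trials,
            "spur_radius_nm": self.spur_radius,
            "spur_radius_percentile": self.spur_radius_percentile,
            "spur_radius_sensitivity_nm": self.spur_radius_sensitivity,
            "mean_event_number": self.mean_event_number,
            "mean_event_number_se": self.mean_event_number_se,
            "relocalised_fraction": self.relocalised_fraction,
            "relocalised_fraction_se": self.relocalised_fraction_se,
            "mean_additional_electrons": self.mean_additional_electrons,
            "maxwellian_ks": self.maxwellian_ks,
            "temperature_K": self.temperature,
        }


def summarise(
    histories: Sequence[HistoryRecord],
    *,
    temperature: float = 300.0,
    relocalisation_radius: float = 1.0,
    percentile: float = 0.95,
) -> SpurSummary:
    """Reduce an ensemble at one deposition energy to its spur observables."""
    if len(histories) < 2:
        raise ValueError("need at least two histories")
    hist = radial_distribution(histories)
    radius = spur_radius(hist, percentile, exclude_below=relocalisation_radius)
    sensitivity = {
        f"{p:.2f}": spur_radius(hist, p, exclude_below=relocalisation_radius)
        for p in (0.90, 0.95, 0.99)
    }
    mean_ev, se_ev = mean_event_number(histories)
    per_trial_reloc = np.array(
        [
            np.mean(h.terminal_distances() < relocalisation_radius)
            for h in histories
        ]
    )
    energies = np.concatenate([h.terminal_kinetic_energies() for h in histories])
    n_add = np.array(
        [sum(1 for e in h.electrons if e.generation == "additional") for h in histories]
    )
    return SpurSummary(
        deposition_energy=histories[0].deposition_energy,
        n_trials=len(histories),
        spur_radius=radius,
        spur_radius_percentile=percentile,
        spur_radius_sensitivity=sensitivity,
        mean_event_number=mean_ev,
        mean_event_number_se=se_ev,
        relocalised_fraction=float(per_trial_reloc.mean()),
        relocalised_fraction_se=float(
            per_trial_reloc.std(ddof=1) / math.sqrt(len(per_trial_reloc))
        ),
        mean_additional_electrons=float(n_add.mean()),
        maxwellian_ks=maxwellian_distance(energies, temperature)
        if energies.size >= 50
        else float("nan"),
        temperature=temperature,
    )
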