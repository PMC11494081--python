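"""Default cross-section bundle and bundle file I/O.

The shipped bundle is a self-consistent stand-in for the literature
parameterisation of the liquid-water dielectric function: 11 Drude oscillators
(5 ionisation shells, 6 electronic excitations) whose *total* energy-loss
function peaks at 21.4 eV and decreases monotonically above 22 eV, plus
synthetic molecular-excitation tables (rotation, intra-/inter-molecular
vibration) with magnitudes and shapes typical of the condensed-phase data sets
used in track-structure work.  All constants are frozen here; the generator is
deterministic.  A literature parameter set can be loaded through the same file
format for quantitative work.

Bundle layout on disk: one JSON document (format tag ``spurdyn-bundle/1``)
plus 2-column columnar text tables (energy_eV, sigma_cm2) with ``#`` headers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .constants import ETA_C_LOW, WATER_DENSITY_CM3, WATER_EFFECTIVE_Z
from .xs import ChannelSpec, CrossSectionBundle, DrudeTerm, TabulatedChannel

FORMAT_TAG = "spurdyn-bundle/1"

# (channel_id, kind, transition energy eV, amplitude eV^2, drude center eV, width eV)
# Centers sit at the mean transition energies; the collective oscillator is
# centered 0.05 eV high so the *summed* ELF (including the low-energy tails)
# peaks at 21.4 eV on a 0.05 eV grid.
_DRUDE_SET = [
    ("exc_a1b1", "electronic_excitation", 8.4, 1.2, 8.4, 1.8),
    ("exc_b1a1", "electronic_excitation", 10.1, 1.5, 10.1, 2.2),
    ("exc_ryd_ab", "electronic_excitation", 11.25, 2.0, 11.25, 2.6),
    ("exc_ryd_cd", "electronic_excitation", 11.93, 2.5, 11.93, 3.0),
    ("exc_diffuse", "electronic_excitation", 14.1, 10.0, 14.1, 3.6),
    ("exc_collective", "electronic_excitation", 21.4, 71.9, 21.45, 3.2),
    ("ion_1b1", "ionisation", 10.9, 3.0, 10.9, 2.8),
    ("ion_3a1", "ionisation", 13.5, 6.0, 13.5, 4.0),
    ("ion_1b2", "ionisation", 17.0, 16.0, 17.0, 5.0),
    ("ion_2a1", "ionisation", 26.3, 40.0, 26.3, 9.0),
    ("ion_1a1", "ionisation", 533.0, 260.0, 533.0, 160.0),
]

# (channel_id, kind, quantum eV, peak sigma cm^2, peak energy eV, rise exp, fall exp)
_MOLECULAR_SET = [
    ("rotation", "rotation", 0.010, 1.5e-15, 0.03, 1.0, 1.0),
    ("inter_vibration", "inter_vibration", 0.092, 4.0e-16, 0.40, 1.5, 1.2),
    ("intra_vibration", "intra_vibration", 0.200, 2.5e-16, 2.00, 1.5, 1.1),
]

#: log-spaced molecular table grid, eV
TABLE_GRID = np.logspace(-4, 3, 200)


def _molecular_sigma(e: np.ndarray, delta: float, pk: float, epk: float, p: float, q: float):
    """Smooth thresholded peak: zero below the quantum, ~E^-q tail above."""
    e = np.asarray(e, dtype=float)
    x = e / epk
    with np.errstate(divide="ignore", invalid="ignore"):
        shape = 2.0 / (x ** (-p) + x ** q)
        onset = np.where(e > delta, (1.0 - delta / np.maximum(e, delta)) ** 1.5, 0.0)
    return pk * shape * onset


def default_bundle(seed: int = 0) -> CrossSectionBundle:
    """Construct the default in-memory bundle (deterministic; seed recorded only)."""
    drude = [DrudeTerm(cid, amp, ctr, wid) for cid, _, _, amp, ctr, wid in _DRUDE_SET]
    channels = [
        ChannelSpec(cid, kind, te, spawns_electron=(kind == "ionisation"))
        for cid, kind, te, _, _, _ in _DRUDE_SET
    ]
    tables = []
    for cid, kind, delta, pk, epk, p, q in _MOLECULAR_SET:
        spec = ChannelSpec(cid, kind, delta)
        sigma = _molecular_sigma(TABLE_GRID, delta, pk, epk, p, q)
        tables.append(TabulatedChannel(spec, TABLE_GRID.copy(), sigma))
        channels.append(spec)
    channels.append(ChannelSpec("elastic", "elastic", 0.0))
    return CrossSectionBundle(
        drude_terms=drude,
        channels=channels,
        tables=tables,
        molecular_density=WATER_DENSITY_CM3,
        effective_Z=WATER_EFFECTIVE_Z,
        eta_c_low=ETA_C_LOW,
    )


def write_bundle(bundle: CrossSectionBundle, path: str | Path, seed: int = 0) -> Path:
    """Write a bundle as bundle.json + tables/*.txt under ``path``."""
    root = Path(path)
    (root / "tables").mkdir(parents=True, exist_ok=True)
    doc = {
        "format": FORMAT_TAG,
        "seed": int(seed),
        "molecular_density_cm3": bundle.molecular_density,
        "effective_Z": bundle.effective_Z,
        "eta_c_low": bundle.eta_c_low,
        "screening_form": bundle.screening_form,
        "disabled_channels": list(bundle.disabled_channels),
        "drude_terms": [
            {
                "channel_id": t.channel_id,
                "amplitude_eV2": t.amplitude,
                "center_eV": t.center,
                "width_eV": t.width,
            }
            for t in bundle.drude_terms
        ],
        "channels": [
            {
                "id": c.channel_id,
                "kind": c.kind,
                "transition_energy_eV": c.transition_energy,
                "spawns_electron": c.spawns_electron,
            }
            for c in bundle.channels
        ],
        "tables": {
            t.channel_spec.channel_id: f"tables/{t.channel_spec.channel_id}.txt"
            for t in bundle.tables
        },
    }
    for t in bundle.tables:
        lines = [
            f"# spurdyn molecular-excitation table: {t.channel_spec.channel_id}",
            "# energy_eV sigma_cm2",
        ]
        for e, s in zip(t.energy_grid, t.sigma_values):
            lines.append(f"{float(e)!r} {float(s)!r}")
        (root / "tables" / f"{t.channel_spec.channel_id}.txt").write_text(
            "\n".join(lines) + "\n"
        )
    (root / "bundle.json").write_text(json.dumps(doc, indent=1))
    return root / "bundle.json"


def load_bundle(path: str | Path) -> CrossSectionBundle:
    """Read a bundle written by :func:`write_bundle` (bit-exact round trip)."""
    p = Path(path)
    if p.is_dir():
        p = p / "bundle.json"
    doc = json.loads(p.read_text())
    if doc.get("format") != FORMAT_TAG:
        raise ValueError(f"unsupported bundle format {doc.get('format')!r}")
    drude = [
        DrudeTerm(d["channel_id"], d["amplitude_eV2"], d["center_eV"], d["width_eV"])
        for d in doc["drude_terms"]
    ]
    channels = [
        ChannelSpec(
            c["id"], c["kind"], c["transition_energy_eV"], c.get("spawns_electron", False)
        )
        for c in doc["channels"]
    ]
    by_id = {c.channel_id: c for c in channels}
    tables = []
    for cid, rel in doc["tables"].items():
        rows = []
        for line in (p.parent / rel).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            e, s = line.split()
            rows.append((float(e), float(s)))
        arr = np.array(rows)
        tables.append(TabulatedChannel(by_id[cid], arr[:, 0], arr[:, 1]))
    return CrossSectionBundle(
        drude_terms=drude,
        channels=channels,
        tables=tables,
        molecular_density=doc["molecular_density_cm3"],
        effective_Z=doc["effective_Z"],
        eta_c_low=doc["eta_c_low"],
        screening_form=doc.get("screening_form", "tau_tau_plus_1"),
        disabled_channels=tuple(doc.get("disabled_channels", ())),
    )


def generate_fixture_bundle(path: str | Path, seed: int = 0) -> Path:
    """Write the default fixture bundle to ``path`` and return bundle.json."""
    return write_bundle(default_bundle(seed), path, seed=seed)


def validate_bundle(bundle: CrossSectionBundle) -> list[str]:
    """Run structural checks; return a list of human-readable problems."""
    problems: list[str] = []
    for t in bundle.tables:
        if not np.all(np.diff(t.energy_grid) > 0):
            problems.append(f"{t.channel_spec.channel_id}: grid not increasing")
        if np.any(t.sigma_values < 0):
            problems.append(f"{t.channel_spec.channel_id}: negative sigma")
    for term in bundle.drude_terms:
        if term(0.0) != 0.0:
            problems.append(f"{term.channel_id}: ELF term non-zero at omega=0")
    kinds = [c.kind for c in bundle.channels]
    if kinds.count("elastic") != 1:
        problems.append("bundle must have exactly one elastic channel")
    return problems
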