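"""Vectorised stepping kernel and precomputed rate tables for the transport engine.

The engine advances every live electron of one trial with velocity-Verlet
steps of the (attosecond-scale) time step in the screened field of its own
parent cation, applies the per-step stochastic collision test
1 - exp(-ds/lambda) > k, and dispatches sampled channels: Moliere elastic
exchange with the 300 K bath, quantum losses (and detailed-balance gains) for
the molecular channels, fixed-transition losses with kinematic deflection for
electronic excitations, and electron spawning for ionisations.

All interaction rates are carried as per-channel inverse-mean-free-path tables
on a log-energy grid (linear interpolation in the log-energy index, flat
beyond the edges), built once per bundle/configuration from the xs module, so
the in-kernel physics and the public cross-section API agree by construction.
Energy-transfer sampling for ionisation uses precomputed inverse-CDF tables of
the Ashley integrand.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .constants import (
    CM2_TO_NM2,
    K_BOLTZMANN,
    K_COULOMB,
    M0C2,
    M_ELECTRON,
    M_WATER,
    PER_CM_TO_PER_NM,
)
from .xs import (
    CrossSectionBundle,
    ELF_KINDS,
    MOLECULAR_KINDS,
    ashley_imfp,
    energy_transfer_density,
    sigma_elastic,
)

# channel kind codes used inside the kernel
KIND_ELASTIC = 0
KIND_IONISATION = 1
KIND_ELECTRONIC = 2
KIND_ROTATION = 3
KIND_INTRA_VIB = 4
KIND_INTER_VIB = 5
KIND_SUPERELASTIC = 6

_KIND_CODES = {
    "elastic": KIND_ELASTIC,
    "ionisation": KIND_IONISATION,
    "electronic_excitation": KIND_ELECTRONIC,
    "rotation": KIND_ROTATION,
    "intra_vibration": KIND_INTRA_VIB,
    "inter_vibration": KIND_INTER_VIB,
}

N_ENERGY_NODES = 512
LOG_E_MIN = -5.0
LOG_E_MAX = 3.0
N_QUANTILES = 65


@dataclass
class EngineTables:
    """Precomputed per-channel rates and samplers on a log-energy grid."""

    energy_nodes: np.ndarray
    log_e0: float
    dlog_e: float
    channel_ids: list[str]
    kind_code: np.ndarray          # int64 (nch,)
    delta: np.ndarray              # float64 (nch,) transition energy / quantum
    spawns: np.ndarray             # int64 (nch,)
    imfp_ch: np.ndarray            # float64 (nch, nE) per nm
    imfp_tot: np.ndarray           # float64 (nE,) per nm
    icdf_idx: np.ndarray           # int64 (nch,) row into icdf or -1
    icdf: np.ndarray               # float64 (nion, nE, nQ) energy transfer, eV
    eta_prefactor: float           # eta_c * 1.7e-5 * Z^(2/3)
    options: dict = field(default_factory=dict)


def build_engine_tables(
    bundle: CrossSectionBundle,
    *,
    temperature: float = 300.0,
    detailed_balance: bool = True,
    transfer_weight_L: bool = True,
) -> EngineTables:
    """Build (or fetch from the bundle's cache) the kernel rate tables."""
    key = (temperature, detailed_balance, transfer_weight_L)
    cache = bundle.__dict__.setdefault("_engine_table_cache", {})
    if key in cache:
        return cache[key]

    n_nm3 = bundle.molecular_density * 1e-21
    e_nodes = np.logspace(LOG_E_MIN, LOG_E_MAX, N_ENERGY_NODES)
    log_e0 = LOG_E_MIN
    dlog_e = (LOG_E_MAX - LOG_E_MIN) / (N_ENERGY_NODES - 1)
    kT = K_BOLTZMANN * temperature

    ids: list[str] = []
    kinds: list[int] = []
    deltas: list[float] = []
    spawns: list[int] = []
    rows: list[np.ndarray] = []
    icdf_idx: list[int] = []
    icdf_rows: list[np.ndarray] = []

    for spec in bundle.active_channels():
        ids.append(spec.channel_id)
        kinds.append(_KIND_CODES[spec.kind])
        deltas.append(spec.transition_energy)
        spawns.append(int(spec.spawns_electron))
        if spec.kind == "elastic":
            rows.append(
                np.asarray(sigma_elastic(e_nodes, bundle)) * CM2_TO_NM2 * n_nm3
            )
            icdf_idx.append(-1)
        elif spec.kind in ELF_KINDS:
            # transport convention: threshold both ionisation and electronic kinds
            imfp = np.array(
                [
                    ashley_imfp(bundle, e, spec.channel_id, thresholded=True)
                    for e in e_nodes
                ]
            )
            rows.append(imfp * PER_CM_TO_PER_NM)
            if spec.kind == "ionisation":
                icdf_idx.append(len(icdf_rows))
                icdf_rows.append(
                    _build_icdf_rows(bundle, spec, e_nodes, transfer_weight_L)
                )
            else:
                icdf_idx.append(-1)
        else:  # molecular table
            sigma = np.asarray(bundle.table(spec.channel_id)(e_nodes))
            rows.append(sigma * CM2_TO_NM2 * n_nm3)
            icdf_idx.append(-1)

    if detailed_balance:
        # super-elastic companions: sigma_sup(E) v(E) f_M(E) = sigma_exc(E') v(E') f_M(E')
        # with E' = E + quantum  =>  imfp_sup(E) = imfp_exc(E+d) (E+d)/E exp(-d/kT)
        base = list(zip(ids, kinds, deltas, rows))
        for cid, kind, d, row in base:
            if kind in (KIND_ROTATION, KIND_INTRA_VIB, KIND_INTER_VIB):
                shifted = np.interp(e_nodes + d, e_nodes, row)
                sup = shifted * (e_nodes + d) / e_nodes * math.exp(-d / kT)
                ids.append(cid + "+gain")
                kinds.append(KIND_SUPERELASTIC)
                deltas.append(d)
                spawns.append(0)
                rows.append(sup)
                icdf_idx.append(-1)

    imfp_ch = np.vstack(rows)
    icdf = (
        np.stack(icdf_rows)
        if icdf_rows
        else np.zeros((0, N_ENERGY_NODES, N_QUANTILES))
    )
    tables = EngineTables(
        energy_nodes=e_nodes,
        log_e0=log_e0,
        dlog_e=dlog_e,
        channel_ids=ids,
        kind_code=np.asarray(kinds, dtype=np.int64),
        delta=np.asarray(deltas, dtype=np.float64),
        spawns=np.asarray(spawns, dtype=np.int64),
        imfp_ch=np.ascontiguousarray(imfp_ch),
        imfp_tot=np.ascontiguousarray(imfp_ch.sum(axis=0)),
        icdf_idx=np.asarray(icdf_idx, dtype=np.int64),
        icdf=np.ascontiguousarray(icdf),
        eta_prefactor=bundle.eta_c_low * 1.7e-5 * bundle.effective_Z ** (2.0 / 3.0),
        options={
            "temperature": temperature,
            "detailed_balance": detailed_balance,
            "transfer_weight_L": transfer_weight_L,
        },
    )
    cache[key] = tables
    return tables


def _build_icdf_rows(bundle, spec, e_nodes, weight_L) -> np.ndarray:
    """Inverse-CDF table of the energy transfer for one ionisation channel."""
    quantiles = np.linspace(0.0, 1.0, N_QUANTILES)
    out = np.zeros((len(e_nodes), N_QUANTILES))
    for i, e in enumerate(e_nodes):
        if e < spec.transition_energy:
            continue
        w, dens = energy_transfer_density(
            bundle, e, spec.channel_id, weight_L=weight_L, n_grid=1024
        )
        cum = np.concatenate(
            [[0.0], np.cumsum((dens[1:] + dens[:-1]) * 0.5 * np.diff(w))]
        )
        if cum[-1] <= 0:
            continue
        out[i] = np.interp(quantiles, cum / cum[-1], w)
    return out


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(inline="always")
def _interp_row(row, x):
    # x is the fractional node index, already clamped by caller
    i0 = int(x)
    f = x - i0
    return row[i0] * (1.0 - f) + row[i0 + 1] * f


@njit(inline="always")
def _node_index(e, log_e0, dlog_e, n_nodes):
    x = (math.log10(max(e, 1e-300)) - log_e0) / dlog_e
    if x < 0.0:
        x = 0.0
    elif x > n_nodes - 1.000001:
        x = n_nodes - 1.000001
    return x


@njit(inline="always")
def _rotate_about(vx, vy, vz, ct, st, cp, sp):
    """Rotate vector v to polar angle theta / azimuth phi about its own axis."""
    norm = math.sqrt(vx * vx + vy * vy + vz * vz)
    if norm == 0.0:
        return vx, vy, vz
    ux, uy, uz = vx / norm, vy / norm, vz / norm
    if abs(uz) < 0.99:
        hx, hy, hz = 0.0, 0.0, 1.0
    else:
        hx, hy, hz = 1.0, 0.0, 0.0
    e1x = uy * hz - uz * hy
    e1y = uz * hx - ux * hz
    e1z = ux * hy - uy * hx
    n1 = math.sqrt(e1x * e1x + e1y * e1y + e1z * e1z)
    e1x, e1y, e1z = e1x / n1, e1y / n1, e1z / n1
    e2x = uy * e1z - uz * e1y
    e2y = uz * e1x - ux * e1z
    e2z = ux * e1y - uy * e1x
    nx = ct * ux + st * (cp * e1x + sp * e2x)
    ny = ct * uy + st * (cp * e1y + sp * e2y)
    nz = ct * uz + st * (cp * e1z + sp * e2z)
    return nx * norm, ny * norm, nz * norm


@njit(inline="always")
def _moliere_eta(e, eta_prefactor):
    tau = e / M0C2
    return eta_prefactor / (tau * (tau + 1.0))


@njit(inline="always")
def _moliere_cos_theta(eta, u):
    inv = 1.0 / (2.0 * eta) - u * (1.0 / (2.0 * eta) - 1.0 / (2.0 + 2.0 * eta))
    t = 1.0 / inv
    c = 1.0 + 2.0 * eta - t
    if c > 1.0:
        c = 1.0
    elif c < -1.0:
        c = -1.0
    return c


@njit(inline="always")
def _momentum_transfer_ratio(eta):
    # sigma_mom / sigma_elas = 2 eta (1+eta) [ln(1+1/eta) - 1/(1+eta)]
    return 2.0 * eta * (1.0 + eta) * (math.log1p(1.0 / eta) - 1.0 / (1.0 + eta))


@njit(inline="always")
def _kinematic_sin2(e1, e2):
    # primary and secondary deflection angles from energy/momentum conservation
    frac = e2 / e1
    s2p = frac / ((1.0 - frac) * e1 / (2.0 * M0C2) + 1.0)
    s2s = (1.0 - frac) / (1.0 + e2 / (2.0 * M0C2))
    if s2p > 1.0:
        s2p = 1.0
    if s2s > 1.0:
        s2s = 1.0
    return s2p, s2s


@njit
def run_trial_kernel(
    seed,
    n_steps,
    dt,
    e_dep,
    a_core,
    kT,
    eps_table,
    log_e0,
    dlog_e,
    imfp_tot,
    imfp_ch,
    kind_code,
    delta,
    icdf_idx,
    icdf,
    eta_prefactor,
    elastic_mode,       # 0 kinematic vector exchange, 1 scalar mean (Eq.-5 style)
    log_all_events,
    # outputs
    e_pos,              # (maxe, 3)
    e_vel,              # (maxe, 3)
    e_acc,              # (maxe, 3) scratch
    e_parent,           # (maxe,) int64 cation index
    e_gen,              # (maxe,) 0 initial / 1 additional
    e_birth_step,       # (maxe,)
    e_birth_ke,         # (maxe,)
    c_pos,              # (maxc, 3)
    c_birth_step,       # (maxc,)
    ev_time,
    ev_pos,
    ev_channel,
    ev_transfer,
    ev_gen,
    counts,             # (nch,) int64
    esums,              # (4,) loss, gain, elastic_net, n_clamped
    out_meta,           # (4,) int64: n_e, n_cat, n_ev, overflow flag
):
    np.random.seed(seed)
    maxe = e_pos.shape[0]
    maxc = c_pos.shape[0]
    ev_cap = ev_time.shape[0]
    n_nodes = imfp_tot.shape[0]
    nch = imfp_ch.shape[0]
    nq = icdf.shape[2]

    # initial electron: at origin (its parent cation's centre), moving along +z
    n_e = 1
    n_cat = 1
    n_ev = 0
    overflow = 0
    for k in range(3):
        e_pos[0, k] = 0.0
        e_vel[0, k] = 0.0
        e_acc[0, k] = 0.0
        c_pos[0, k] = 0.0
    e_vel[0, 2] = math.sqrt(2.0 * e_dep / M_ELECTRON)
    e_parent[0] = 0
    e_gen[0] = 0
    e_birth_step[0] = 0
    e_birth_ke[0] = e_dep
    c_birth_step[0] = 0

    inv_a3 = 1.0 / (a_core * a_core * a_core)
    sqrt_kT_over_M = math.sqrt(kT / M_WATER)
    two_m_over_M = 2.0 * M_ELECTRON / M_WATER

    for step in range(n_steps):
        n_e_now = n_e  # electrons born this step start next step
        for i in range(n_e_now):
            if e_birth_step[i] > step:
                continue
            age = step - c_birth_step[e_parent[i]]
            epsr = eps_table[age]

            # velocity Verlet: drift with cached acceleration
            px = e_pos[i, 0] + e_vel[i, 0] * dt + 0.5 * e_acc[i, 0] * dt * dt
            py = e_pos[i, 1] + e_vel[i, 1] * dt + 0.5 * e_acc[i, 1] * dt * dt
            pz = e_pos[i, 2] + e_vel[i, 2] * dt + 0.5 * e_acc[i, 2] * dt * dt
            cp0 = c_pos[e_parent[i], 0]
            cp1 = c_pos[e_parent[i], 1]
            cp2 = c_pos[e_parent[i], 2]
            rx = px - cp0
            ry = py - cp1
            rz = pz - cp2
            r2 = rx * rx + ry * ry + rz * rz
            r = math.sqrt(r2)
            if r >= a_core:
                coef = -K_COULOMB / (epsr * r2 * r)
            else:
                coef = -K_COULOMB * inv_a3 / epsr
            ax = coef * rx / M_ELECTRON
            ay = coef * ry / M_ELECTRON
            az = coef * rz / M_ELECTRON
            vx = e_vel[i, 0] + 0.5 * (e_acc[i, 0] + ax) * dt
            vy = e_vel[i, 1] + 0.5 * (e_acc[i, 1] + ay) * dt
            vz = e_vel[i, 2] + 0.5 * (e_acc[i, 2] + az) * dt
            e_pos[i, 0] = px
            e_pos[i, 1] = py
            e_pos[i, 2] = pz
            e_acc[i, 0] = ax
            e_acc[i, 1] = ay
            e_acc[i, 2] = az

            v2 = vx * vx + vy * vy + vz * vz
            energy = 0.5 * M_ELECTRON * v2
            speed = math.sqrt(v2)
            ds = speed * dt

            x = _node_index(energy, log_e0, dlog_e, n_nodes)
            lam_inv = _interp_row(imfp_tot, x)
            collided = False
            if lam_inv > 0.0:
                p = -math.expm1(-ds * lam_inv)
                if np.random.random() < p:
                    collided = True

            if collided:
                # channel sampling by interpolated per-channel rates
                target = np.random.random() * lam_inv
                acc_rate = 0.0
                ch = nch - 1
                for c in range(nch):
                    acc_rate += _interp_row(imfp_ch[c], x)
                    if target <= acc_rate:
                        ch = c
                        break
                kind = kind_code[ch]
                de_logged = 0.0
                valid = True

                if kind == KIND_ELASTIC:
                    eta = _moliere_eta(energy, eta_prefactor)
                    ct = _moliere_cos_theta(eta, np.random.random())
                    st = math.sqrt(max(1.0 - ct * ct, 0.0))
                    phi = 2.0 * math.pi * np.random.random()
                    cphi = math.cos(phi)
                    sphi = math.sin(phi)
                    if elastic_mode == 0:
                        # full two-body exchange with a Maxwellian molecule
                        wx = sqrt_kT_over_M * np.random.normal(0.0, 1.0)
                        wy = sqrt_kT_over_M * np.random.normal(0.0, 1.0)
                        wz = sqrt_kT_over_M * np.random.normal(0.0, 1.0)
                        gx = vx - wx
                        gy = vy - wy
                        gz = vz - wz
                        gx, gy, gz = _rotate_about(gx, gy, gz, ct, st, cphi, sphi)
                        mtot = M_ELECTRON + M_WATER
                        cmx = (M_ELECTRON * vx + M_WATER * wx) / mtot
                        cmy = (M_ELECTRON * vy + M_WATER * wy) / mtot
                        cmz = (M_ELECTRON * vz + M_WATER * wz) / mtot
                        frac = M_WATER / mtot
                        nvx = cmx + frac * gx
                        nvy = cmy + frac * gy
                        nvz = cmz + frac * gz
                        new_e = 0.5 * M_ELECTRON * (nvx * nvx + nvy * nvy + nvz * nvz)
                        esums[2] += new_e - energy
                        de_logged = energy - new_e
                        vx, vy, vz = nvx, nvy, nvz
                        energy = new_e
                    else:
                        # scalar mean-transfer form with an independently drawn E_mol
                        vx, vy, vz = _rotate_about(vx, vy, vz, ct, st, cphi, sphi)
                        n1 = np.random.normal(0.0, 1.0)
                        n2 = np.random.normal(0.0, 1.0)
                        n3 = np.random.normal(0.0, 1.0)
                        e_mol = 0.5 * kT * (n1 * n1 + n2 * n2 + n3 * n3)
                        ratio = _momentum_transfer_ratio(eta)
                        d_e = two_m_over_M * ratio * (energy - e_mol)
                        new_e = energy - d_e
                        if new_e < 0.0:
                            new_e = 0.0
                            esums[3] += 1.0
                        scale = math.sqrt(new_e / energy) if energy > 0.0 else 0.0
                        vx *= scale
                        vy *= scale
                        vz *= scale
                        esums[2] += new_e - energy
                        de_logged = energy - new_e
                        energy = new_e

                elif kind == KIND_ROTATION or kind == KIND_INTRA_VIB or kind == KIND_INTER_VIB:
                    d = delta[ch]
                    if energy > d:
                        new_e = energy - d
                        scale = math.sqrt(new_e / energy)
                        vx *= scale
                        vy *= scale
                        vz *= scale
                        esums[0] += d
                        de_logged = d
                        energy = new_e
                    else:
                        valid = False  # threshold-interpolation leak: no event

                elif kind == KIND_SUPERELASTIC:
                    d = delta[ch]
                    new_e = energy + d
                    scale = math.sqrt(new_e / energy) if energy > 0.0 else 0.0
                    if scale > 0.0:
                        vx *= scale
                        vy *= scale
                        vz *= scale
                        esums[1] += d
                        de_logged = -d
                        energy = new_e
                    else:
                        valid = False

                elif kind == KIND_ELECTRONIC:
                    d = delta[ch]
                    if energy >= d:
                        s2p, _s2s = _kinematic_sin2(energy, d)
                        sp_ = math.sqrt(s2p)
                        ctp = math.sqrt(max(1.0 - s2p, 0.0))
                        phi = 2.0 * math.pi * np.random.random()
                        vx, vy, vz = _rotate_about(
                            vx, vy, vz, ctp, sp_, math.cos(phi), math.sin(phi)
                        )
                        new_e = energy - d
                        scale = math.sqrt(new_e / energy) if energy > 0.0 else 0.0
                        vx *= scale
                        vy *= scale
                        vz *= scale
                        esums[0] += d
                        de_logged = d
                        energy = new_e
                    else:
                        valid = False

                else:  # ionisation
                    d = delta[ch]
                    if energy >= d and icdf_idx[ch] >= 0:
                        row = icdf_idx[ch]
                        # bilinear inverse-CDF lookup: energy index x, quantile u
                        uq = np.random.random() * (nq - 1)
                        iq = int(uq)
                        if iq > nq - 2:
                            iq = nq - 2
                        fq = uq - iq
                        ie = int(x)
                        fe = x - ie
                        w_lo = icdf[row, ie, iq] * (1.0 - fq) + icdf[row, ie, iq + 1] * fq
                        w_hi = (
                            icdf[row, ie + 1, iq] * (1.0 - fq)
                            + icdf[row, ie + 1, iq + 1] * fq
                        )
                        w = w_lo * (1.0 - fe) + w_hi * fe
                        if w > 0.5 * energy:
                            w = 0.5 * energy
                        if w <= 0.0:
                            valid = False
                        else:
                            s2p, s2s = _kinematic_sin2(energy, w)
                            stp = math.sqrt(s2p)
                            ctp = math.sqrt(max(1.0 - s2p, 0.0))
                            sts = math.sqrt(s2s)
                            cts = math.sqrt(max(1.0 - s2s, 0.0))
                            phi = 2.0 * math.pi * np.random.random()
                            cphi = math.cos(phi)
                            sphi = math.sin(phi)
                            # secondary: theta_s off the pre-collision direction,
                            # azimuth offset pi (coplanar momentum balance)
                            if n_e < maxe and n_cat < maxc:
                                sx, sy, sz = _rotate_about(
                                    vx, vy, vz, cts, sts, -cphi, -sphi
                                )
                                snorm = math.sqrt(sx * sx + sy * sy + sz * sz)
                                sspeed = math.sqrt(2.0 * w / M_ELECTRON)
                                j = n_e
                                e_pos[j, 0] = px
                                e_pos[j, 1] = py
                                e_pos[j, 2] = pz
                                e_vel[j, 0] = sx / snorm * sspeed
                                e_vel[j, 1] = sy / snorm * sspeed
                                e_vel[j, 2] = sz / snorm * sspeed
                                e_acc[j, 0] = 0.0
                                e_acc[j, 1] = 0.0
                                e_acc[j, 2] = 0.0
                                cidx = n_cat
                                c_pos[cidx, 0] = px
                                c_pos[cidx, 1] = py
                                c_pos[cidx, 2] = pz
                                c_birth_step[cidx] = step + 1
                                e_parent[j] = cidx
                                e_gen[j] = 1
                                e_birth_step[j] = step + 1
                                e_birth_ke[j] = w
                                n_cat += 1
                                n_e += 1
                            else:
                                overflow = 1
                            # primary deflection and loss
                            vx, vy, vz = _rotate_about(vx, vy, vz, ctp, stp, cphi, sphi)
                            new_e = energy - w
                            scale = math.sqrt(new_e / energy) if energy > 0.0 else 0.0
                            vx *= scale
                            vy *= scale
                            vz *= scale
                            esums[0] += w
                            de_logged = w
                            energy = new_e
                    else:
                        valid = False

                if valid:
                    counts[ch] += 1
                    if (
                        kind == KIND_IONISATION
                        or kind == KIND_ELECTRONIC
                        or log_all_events == 1
                    ):
                        if n_ev < ev_cap:
                            ev_time[n_ev] = (step + 1) * dt
                            ev_pos[n_ev, 0] = px
                            ev_pos[n_ev, 1] = py
                            ev_pos[n_ev, 2] = pz
                            ev_channel[n_ev] = ch
                            ev_transfer[n_ev] = de_logged
                            ev_gen[n_ev] = e_gen[i]
                            n_ev += 1
                        else:
                            overflow = 1

            e_vel[i, 0] = vx
            e_vel[i, 1] = vy
            e_vel[i, 2] = vz

    out_meta[0] = n_e
    out_meta[1] = n_cat
    out_meta[2] = n_ev
    out_meta[3] = overflow
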