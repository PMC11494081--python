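# Methods

`spurdyn` simulates the femtosecond physical stage of water radiolysis for a
single 11–30 eV energy deposition: the ejected secondary electron (and any
additional electrons it ionises) is followed in time through liquid water
until a cutoff time, and the terminal ensemble is reduced to the spur
observables — radial electron distributions, collision-frequency maps, mean
inelastic event numbers, the spur radius, and the relocalised fraction.

## Model

### Interaction channels

Inelastic electronic channels (five ionisation shells: 1b1 10.9, 3a1 13.5,
1b2 17.0, 2a1 26.3, 1a1 533 eV; six electronic excitations: A1B1 8.4,
B1A1 10.1, Rydberg A+B 11.25, Rydberg C+D 11.93, diffuse band 14.1,
collective 21.4 eV) are driven by the liquid-water energy-loss function
Im(−1/ε(0, ω′)), parameterised as a sum of Drude oscillators with one
oscillator per channel. Per-channel inverse mean free paths follow Ashley's
optical-data formula

    λ⁻¹(E) = (2πE)⁻¹ ∫₀^{E/2} Im(−1/ε(0, ω′)) L(ω′/E) dω′,
    L(a) = (1−a) ln(4/a) − (7/4)a + a^{3/2} − (33/32)a²,

evaluated in Hartree atomic units (the Hartree factors cancel in the
dimensionless integrand; one division by the Bohr radius converts to cm⁻¹),
and cross sections from σ = 1/(λN) with N = 3.318565 × 10²² cm⁻³.

Two threshold conventions coexist deliberately. *Reported* cross sections
threshold only the ionisation channels at their transition energies (an
electron cannot ionise a shell it cannot pay for; the excitation curves keep
their optical-data tails, as the field's published curves do). The *transport*
tables additionally threshold the electronic excitations, because the engine
charges each such event its fixed mean transition energy and the kinetic
energy ledger must never go negative. The energy transfer ω′ of an ionisation
is sampled from the Ashley integrand ELF_ch(ω′)·L(ω′/E) on (0, E/2] — the
same weight that builds the channel's mean free path — with a configuration
flag to drop the L factor. Transfers below the nominal binding energy are
allowed: the spawned electron then starts too slow to escape its own
cation's well and relocalises, which is exactly the behaviour of the
low-deposition-energy spurs.

Molecular channels (rotation, intra- and inter-molecular vibration) are
tabulated σ(E) curves, interpolated log–log inside their grids and clamped
outside. The bundled synthetic tables use quanta of 0.010, 0.092 and 0.20 eV
and peak magnitudes of 1.5×10⁻¹⁵, 4×10⁻¹⁶ and 2.5×10⁻¹⁶ cm², shapes and
scales typical of the vapour rotational and amorphous-ice vibrational data
sets used in condensed-phase track-structure work.

Elastic scattering is Moliere's screened cross section,

    q(θ) = πZ(Z+1)r_e² ((1−β²)/β⁴) (1−cosθ+2η)⁻²,
    σ_elas = πZ(Z+1)r_e² ((1−β²)/β⁴) / (η(η+1)),
    η = η_c · 1.7×10⁻⁵ Z^{2/3} / (τ(τ+1)),

with Z = 7.42 and η_c = 1.198 below 50 keV. σ_elas equals 2∫₀^π q sinθ dθ
exactly (verified against quadrature), i.e. the pair uses a factor-2 angular
measure, which the momentum-transfer cross section σ_mom = 2∫(1−cosθ)q sinθ dθ
inherits; σ_mom has the closed form 2C[ln(1+1/η) − 1/(1+η)]. There is no
low-energy cutoff anywhere: η grows without bound as E → 0, σ_elas stays
finite (~6.5×10⁻¹⁶ cm²) and scattering becomes isotropic. The screening
denominator τ(τ+1) is kept verbatim; the conventional τ(τ+2) form is a
configuration switch (`screening_form`), a factor-2 effect on η at eV
energies.

### Elastic energy exchange and detailed balance

The mean elastic energy transfer to a molecule of kinetic energy E_mol is
ΔE ≈ (2m/M)(σ_mom/σ_elas)(E_e − E_mol), a few µeV per collision at thermal
energies. Applied literally as a deterministic per-collision transfer, this
map is an AR(1) contraction: an ensemble collapses onto a narrow peak at
(3/2)kT and can never *spread* into the Maxwell–Boltzmann distribution.
The engine's default therefore performs the full two-body kinematic exchange:
the molecule's velocity vector is drawn from the 300 K Maxwellian, the
relative velocity is rotated by the Moliere-sampled angle, and the
post-collision electron velocity follows from momentum conservation. The
ensemble mean of this exchange is exactly the scalar formula above
(σ_mom/σ_elas = ⟨1−cosθ⟩), it satisfies detailed balance, and it holds a
300 K ensemble stationary (tested at KS < 0.02 with 10⁴ electrons). The
scalar form remains available as `elastic_energy_exchange="mean"`.

Because the elastic relaxation rate is only ~2m/M ≈ 6×10⁻⁵ per collision
(~10² collisions in 500 fs), elastic exchange alone cannot thermalise
sub-excitation electrons within the cutoff. What does is the molecular
channels — provided they exchange energy in both directions, as a 300 K bath
must: for every tabulated molecular channel the engine adds a super-elastic
companion whose rate follows from detailed balance,

    λ⁻¹_sup(E) = λ⁻¹_exc(E+Δ) · ((E+Δ)/E) · exp(−Δ/kT),

so the rotational 10 meV ladder performs a detailed-balanced random walk
whose stationary distribution is the Maxwellian. Without this
(`detailed_balance=False`), a downward-only quantum cascade strands every
sub-excitation electron below the lowest quantum and no terminal distribution
can approach 300 K on any timescale. With it, 12.4 eV deposition ensembles
reach KS ≈ 0.02 against the Maxwell–Boltzmann kinetic-energy CDF at the
500 fs cutoff.

### The cation field

Electron and cation are uniformly charged spheres of radius a = 0.099 nm:
U(r) = −k/(ε_r r) outside the core and −k(3a²−r²)/(2ε_r a³) inside
(k = e²/4πε₀ = 1.43996 eV·nm), so the potential is bounded with its minimum
at the origin. ε_r(0) is calibrated so the well depth equals the lowest
ionisation energy, |U(0)| = 10.9 eV, giving ε_r(0) = 3k/(2aD) ≈ 2.0. The
screening relaxes to the static ε_r = 78.4 with a single-exponential law of
time constant 300 fs (all three parameters configurable; the published
dielectric-response function can be dropped in through the same interface).
Each cation carries its own clock, started at the ionisation that created it,
and each electron feels only its own parent cation (two-body rule); there are
no electron–electron or cross-cation forces.

### Transport

Every live electron is integrated with velocity-Verlet steps of Δt = 1 as
(5×10⁵ steps to the 500 fs cutoff). After each step the collision test
1 − exp(−Δs/λ) > k fires with Δs = |v|Δt and λ from the total inverse mean
free path at the current kinetic energy; the channel is then sampled from the
per-channel rate ratios. Ionisation spawns an additional electron at the
collision position — the minimum of its own fresh cation's well — with
kinetic energy ω′, at the conservation angle θ_s off the primary's
pre-collision direction with azimuth opposite the primary's (coplanar
momentum balance); the primary deflects by θ_p. The binary-encounter angles
use sin²θ_p = (E₂/E₁)/[(1−E₂/E₁)E₁/(2m₀c²) + 1] — the denominator is read as
a division because the multiplicative grouping is dimensionally inconsistent,
and this reading recovers the nonrelativistic complementarity
sin²θ_p + sin²θ_s → 1. Electronic excitation deflects by θ_p and charges the
mean transition energy; molecular excitation leaves the direction unchanged.
Relocalisation (terminal distance to the own parent below 1 nm; ties count as
delocalised) is a terminal classification, not an absorbing state — every
electron propagates to the cutoff.

All per-channel rates enter the compiled kernel as inverse-mean-free-path
tables on a 512-node log-energy grid (10⁻⁵–10³ eV), interpolated linearly in
the log-energy index and clamped flat beyond the edges; ionisation energy
transfers come from precomputed 65-quantile inverse-CDF tables. Linear
interpolation keeps total = Σ channels exact at and between the nodes. Near a
channel threshold the interpolation can leak an infinitesimal rate to an
energetically closed channel; such draws are discarded (no event), a bias of
order 10⁻³ of collisions confined to one grid interval.

### Randomness and determinism

One root seed spawns an independent `SeedSequence(root, trial)` stream per
trial, so a history is a pure function of (seed, trial index) — bit-exact on
rerun and independent of the batch size. The Maxwellian bath energies are
drawn as (kT/2)·χ²₃.

## Observables

Terminal distances to the own parent are binned in Δr = 0.1 nm shells,
grouped as initial / additional / all electrons. The collision map bins
ionisation + electronic-excitation event positions by distance from the
origin, normalised per trial. The spur radius is the 95th percentile of the
delocalised (≥ 1 nm) initial-electron distribution, linearly interpolated
within the crossing bin; the percentile is configurable and the 0.90/0.95/0.99
sensitivity is reported alongside, since the near-envelope character of the
estimator is a choice, not something the observable itself fixes. Event
records are kept in full for ionisation and electronic excitation (the kinds
the collision map uses); the 10⁴–10⁵ elastic/molecular events per trial are
aggregated into per-kind counts and energy sums (a `log_all_events` flag
retains everything for small diagnostic runs).

## The synthetic bundle, and what passing tests do and do not show

The shipped cross-section bundle is *synthetic*: eleven Drude oscillators
anchored at the channel transition energies, with amplitudes and widths fixed
once so the total ELF peaks at 21.4 eV (height ≈ 1.2) and decreases
monotonically above 22 eV, plus the molecular tables described above. It
reproduces the printed constraints (peak position, monotone tail, the
diffuse/collective curves exceeding 10⁻¹⁸ cm² in 10–20 eV, thresholds) and
realistic magnitudes, but it is not the literature parameterisation of the
measured dielectric function, whose 11 fitted parameter sets are not printed
in the sources available to this package. Consequences measured with this
bundle: thermalisation, energy bookkeeping, counting statistics and all
closed-form physics are parameterisation-robust; the *quantitative* spur
radii are not — the bundled fixture yields ~20 nm spur radii at 22–30 eV
where the reference results reach ~12 nm at 24 eV, consistent with the
fixture's smaller stopping (its Moliere elastic cross section at 1–10 eV is
several times below condensed-phase measurements, and its electronic channel
strengths carry the same uncertainty). Loading a literature bundle through
the documented file format is the supported route to quantitative radii.
The qualitative structure — most initial electrons delocalising far beyond
1 nm, additional electrons at 22 eV relocalising while those above 25 eV
delocalise to a few nm, the mean inelastic event number crossing 1 near
30 eV — is reproduced.

## Numerical choices

- Δt = 1 as velocity Verlet: symplectic, no secular energy drift; the bounded
  oscillation of the energy error for orbits crossing the harmonic core is
  ~10⁻³ eV and shrinks quadratically with the step (verified at 0.25 as).
  Per-history energy books close to <0.1% of the deposition energy with a
  frozen permittivity.
- Ashley integrals: 3000-point trapezoid on (0, E/2] (checked to 0.1%
  against adaptive quadrature); table energies log-spaced, 200 points,
  10⁻⁴–10³ eV for the molecular fixtures.
- Collisions are placed at the end-of-step position; no sub-step
  interpolation (Δs ≪ λ at these energies).
- Histories are capped at 64 electrons and flagged if ever truncated (the
  11–30 eV regime produces at most a handful).
- No electron-energy floor anywhere; the grid edge at 10⁻⁵ eV is handled by
  flat extrapolation and the super-elastic channels repopulate arbitrarily
  cold electrons.

## Default problem sizes

Ensemble statistics in the shipped tests use 10³ trials per deposition energy
at the full 500 fs / 1 as resolution (~1 minute per energy on one core with
the compiled kernel), which puts the Monte Carlo standard error of the mean
event number near 1%. Larger ensembles scale linearly.

## Known limitations

- Two-body Coulomb only; no electron–electron interaction, no cross-cation
  capture, so relocalisation to *another* parent's core is not modelled.
- The chemical stage (species diffusion/reactions), intermolecular Coulombic
  decay, and multi-body screening corrections are out of scope.
- The collective-excitation channel is retained as an ordinary non-ionising
  loss channel (its physical interpretation is contested); it can be disabled
  per bundle (`disabled_channels`).
- The dielectric relaxation law is a single exponential standing in for the
  published frequency-resolved response; only its endpoints (2.0, 78.4) and
  timescale (300 fs) are constrained here.
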