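# Methods

## The model

`aomflux` implements a curated core stoichiometric model of nitrate-driven
reverse methanogenesis with two compartments (cytoplasm, extracellular),
35 species and 27 reactions. The pathway oxidizes methane to CO₂ through
the reversed methanogenesis sequence (Mcr → Mtr → Mer → Mtd → Mch → Ftr →
Fmd), regenerates the CoM-S-S-CoB heterodisulfide through the cytoplasmic
electron-confurcating HdrABC or the membrane-bound HdrDE, respires to
nitrate through Fqo and the Nar/cytochrome complex, and fixes a small
amount of carbon through Cdh into acetyl-CoA for a lumped biomass drain.
Nrf (nitrite → ammonium, menaquinol-coupled, 6 e⁻) is present but carries
no flux while nitrate is unbounded, since diverting menaquinol away from
the proton-pumping Nar brings no energetic benefit.

Steady-state fluxes solve the linear program max c·v subject to S·v = 0 and
bounds. The assumption is balanced growth: no metabolite accumulates,
including the cofactor pools and the translocated-ion species.

### Ion bookkeeping

Translocated ions are ordinary species: `h_e` and `na_e` exist only on the
extracellular side and are produced or consumed exclusively by membrane
enzymes (Fqo +3 H⁺, Nar +4 H⁺, HdrDE −2 H⁺, Mtr −2 Na⁺, Mrp ±1/±1, the
pseudo-Rnf +4 Na⁺, the ATP synthase −4 ions per ATP, and a passive sodium
uniporter that can only dissipate the gradient). Chemistry protons —
consumed or released by redox reactions without crossing the membrane — are
the cytoplasmic `h_c`, which has a free exchange. This single
representation makes chemiosmotic coupling visible to the LP without double
counting; the `translocations` records on reactions are derived metadata
that the validator cross-checks against the stoichiometry.

The ion ledger counts reactions bearing translocation records. The ATP
synthase is the gradient *consumer* (its yield is reported separately as
its flux) and the sodium leak is not an enzyme-catalyzed translocation, so
neither carries a record; in the reference scenario the ledger total
(28.6) therefore equals the synthase flux times 4 exactly.

The sodium leak exists because the pseudo-Rnf variant pumps 4 Na⁺ per
turnover while the reversed Mtr re-imports only 2: without a dissipative
path the surplus extracellular sodium would violate steady state and the
variant would be artificially infeasible. With Mrp disabled in that
variant, the surplus sodium gradient is simply wasted, which is exactly
what caps the yield at 22.0 protons / 4 = 5.5 ATP.

### Moiety closure as elemental balance

Cofactor cores are pseudo-element tags in species formulas (`Fd`, `Ff`,
`Cm`, `Cb`, `Mq`, `Hm`, `Mf`, `Coa`, `Nd`). Requiring every internal
reaction to be elementally and charge balanced then *implies* closure of
each cofactor pool, and each pool indicator is verifiably a left null-space
vector of the internal stoichiometric matrix. Hydrogen and charge are
tracked in full, which pinned down several easy-to-miss details (e.g.
methenyl-H₄MPT⁺ carries +1; F420 reduction consumes a medium proton at the
Mtd step; HdrABC takes up two medium protons).

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `gam` | 169.9 | mmol ATP/gDW | growth-associated maintenance (biomass drain ATP coefficient) |
| `ngam` | 5.0 | mmol ATP/gDW/h | non-growth maintenance (ATPM lower bound in growth scenarios) |
| `ch4_uptake` | 1.1 | mmol/gDW/h | reference methane uptake; all printed tallies are fluxes at this uptake |
| `ions_per_atp` | 4 | — | translocated ions consumed per ATP by the synthase |
| `fqo_h_out` / `nar_h_out` | 3 / 4 | H⁺/turnover | proton pumping of Fqo and Nar |
| `mtr_na_in` / `hdrde_h_in` | 2 / 2 | ions/turnover | inward sourcing of the reversed Mtr and HdrDE |
| `rnf_na_out` | 4 | Na⁺/turnover | pumping of the hypothetical pseudo-Rnf |
| `biomass_accoa`, `biomass_nadph` | 0.45 | mmol/gDW | lumped biomass precursor demand |

All constants live in `src/aomflux/data/defaults.yaml` and can be
overridden per scenario; none are hard-coded in logic. The 4 ions/ATP
coupling is the ratio implied by the reference numbers themselves
(28.6 ions / 7.15 ATP). The biomass drain is not a composition: it is a
lumped demand calibrated so that at the reference uptake the growth-optimal
solution routes ≈1% of consumed methane carbon into biomass (0.45 mmol
acetyl-CoA/gDW gives 1.01%). NADPH demand is set equal to the acetyl-CoA
demand; it is supplied by F4NR and only weakly affects the optimum.

In ATP-maximization scenarios the NGAM lower bound is released (set to 0)
because the ATP demand reaction is itself the objective; the reported
7.15 is a gross yield, and enforcing NGAM simultaneously would double-count
maintenance.

## Numerical choices

- LP backend: scipy `linprog` (HiGHS) behind a single solve contract;
  feasibility/optimality tolerances 1e-9. An independent cross-check
  against cobrapy/GLPK runs in the test suite.
- Degenerate optima: all reported solutions use parsimonious resolution
  (stage two minimizes Σ|v| at the fixed optimum via a v = p − q split).
  The objective value is provably invariant to this; only the flux pattern
  is selected. This keeps ion ledgers deterministic and reports
  byte-stable.
- Reported numbers in TSV/JSON reports are rounded to 1e-6; in-memory
  solutions are kept at full precision so the steady-state residual
  max |S·v| ≤ 1e-9 holds exactly.
- Directionality: Mcr, HdrABC, HdrDE, Fqo, Nar, Nrf, Cdh, F4NR, the
  synthase and the leak are irreversible in their physiological directions
  (HdrDE in particular is restricted to heterodisulfide formation, since
  menaquinol at −80 mV cannot reduce the −143 mV disulfide couple, and an
  unrestricted reverse direction would open a spurious proton-pumping
  cycle through HdrABC). The C1-carrier chain, Mtr and Mrp are reversible.
- Degenerate inputs: zero-flux solutions give all-zero ledgers and electron
  balances; route shares with both Hdr fluxes zero return an explicit
  `undefined` marker instead of NaN.

## Variants

`R1` (2 Fd_ox + CoM-SH + CoB-SH ⇌ 2 Fd_red + 2 H⁺ + CoM-S-S-CoB) leaves
ferredoxin without a net reoxidation route — the only sink, Cdh, is capped
by the tiny anabolic carbon flux — so the network cannot satisfy
maintenance and growth is infeasible. `R2` alone fails the same way; `R3`
adds a reversible ferredoxin:F420 oxidoreductase
(2 Fd_red + F420 + 2 H⁺ ⇌ 2 Fd_ox + F420H₂) that decouples the two
confurcation half-reactions and restores stoichiometric feasibility —
though the Fd → F420H₂ direction is ≈+27 kJ/mol uphill at standard
potentials, which is why this decoupling is considered implausible and
confurcation essential.

`rnf_swap` removes HdrABC, adds the pseudo-Rnf and disables Mrp, so the
synthase draws only on protons. Counted tallies in that variant are net
H⁺ 22.0 (Fqo 6.6 + Nar 17.6 − HdrDE 2.2) and net Na⁺ +2.2, and the yield
is 22.0/4 = 5.5 ATP.

## Thermodynamics

ΔG = −nFΔE with E in mV and F = 0.09648 kJ mol⁻¹ V⁻¹ scaled per mV; no
unit auto-detection. Default couples: Fd −520, CoM/CoB −143, F420 −380,
menaquinone −80, methanophenazine −165 mV. The NO₃⁻/NO₂⁻ couple (+433 mV)
is the standard textbook value adopted by this package and is flagged
`package-adopted` in the defaults file. The confurcation ΔG composes the
two pair terms: (thiols→F420) + (Fd→F420) = +45.73 − 27.01 = +18.72
kJ/mol at standard potentials. Per-reaction ΔG values for the full
flux-weighted redox-cycle sum (Mcr, Mtr and the Hdr routes) are
user-supplied through `DeltaGTable` rather than invented; the packaged
defaults only provide what the midpoint potentials determine.

## Synthetic networks

The generator emits random balanced networks with the structural features
the analysis relies on — a linear backbone, closed cofactor pairs wired
into backbone steps, ion-pumping reoxidations, an ion-coupled synthase —
and a maximum ATP flux known in closed form
(pumps × ions-per-pump × uptake / ions-per-ATP). It emulates the
*structure* of a respiratory network, not its biology: no branching, no
reversibility games, no thermodynamics. Passing the 100-seed
generator-vs-LP check therefore validates the LP engine, validator and
ledger plumbing, not any biological claim. Generation is a pure function
of its spec (single seeded RNG, no global state); `perturb` only tightens
bounds, so objectives are monotonically non-increasing under perturbation.

## Problem sizes

The core model has 27 reactions; every scenario solves in well under a
second, the whole suite in a few seconds, and the acceptance script in
about a second — sizes chosen because the core analysis is exactly
reproducible at desk scale.

## Known limitations

- The genome-scale context is absent by design: anabolic subsystems,
  gene–protein–reaction rules and the full biomass equation are out of
  scope. Consequently the growth-optimal HdrDE/HdrABC flux split
  (0.01/0.99 here) underestimates the HdrDE share a full reconstruction
  produces via its additional ferredoxin-consuming anabolism.
- Electron closure bookkeeping for growing states attributes all
  non-respired electrons to biomass wholesale (8 × (CH₄ uptake − net CO₂
  export)); it is exact for non-growing (ATP-max) states.
- Only standard-condition ΔG: no concentration corrections, no membrane
  potential or pH-gradient model, no thermodynamic flux analysis.
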