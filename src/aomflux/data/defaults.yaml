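# Versioned defaults for the core reverse-methanogenesis model.
# All tunable constants used by the package live here, never hard-coded in logic.
version: 1

parameters:
  # Growth-associated ATP maintenance, mmol ATP per gDW (stoichiometric
  # coefficient on ATP in the lumped biomass drain).
  gam: 169.9
  # Non-growth-associated ATP maintenance, mmol ATP per gDW per h
  # (lower bound on the ATP demand reaction in growth scenarios).
  ngam: 5.0
  # Reference methane uptake, mmol per gDW per h. All printed ion tallies
  # are fluxes at this uptake.
  ch4_uptake: 1.1
  # Translocated ions (H+ or Na+-equivalents) consumed by the ATP synthase
  # per ATP synthesized.
  ions_per_atp: 4
  # Lumped biomass drain coefficients, mmol per gDW: calibrated so that at
  # the reference methane uptake roughly 1% of consumed methane carbon
  # enters biomass (2 carbons per acetyl-CoA) at the growth optimum.
  biomass_accoa: 0.45
  biomass_nadph: 0.45
  # Default magnitude for unconstrained flux bounds, mmol per gDW per h.
  bound_inf: 1000.0
  # Ion translocation counts per catalytic turnover.
  fqo_h_out: 3
  nar_h_out: 4
  mtr_na_in: 2
  hdrde_h_in: 2
  rnf_na_out: 4

# Midpoint potentials E0' (mV) of the redox couples, and default electrons
# per couple turnover.
redox_couples:
  Fd:     {e0_prime_mv: -520, n_default: 2, source: literature}
  CoM/CoB: {e0_prime_mv: -143, n_default: 2, source: literature}
  F420:   {e0_prime_mv: -380, n_default: 2, source: literature}
  MQ:     {e0_prime_mv: -80,  n_default: 2, source: literature}
  MPh:    {e0_prime_mv: -165, n_default: 2, source: literature}
  # Standard NO3-/NO2- couple; adopted by this package, not taken from the
  # study this model reimplements (which prints no Nar couple potential).
  NO3/NO2: {e0_prime_mv: 433, n_default: 2, source: package-adopted}

# Faraday constant in kJ mol-1 mV-1 per electron (0.09648 kJ/eV).
faraday_kj_per_mv: 0.09648

# Default flux-share weights of the heterodisulfide reductase routes in the
# redox-cycle Gibbs energy sum (HdrDE share 0.183/1.1, HdrABC share 0.917/1.1).
redox_cycle_weights:
  w_de_numerator: 0.183
  w_abc_numerator: 0.917
  denominator: 1.1
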