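# Baseline parameterization of the HER4-JAK2-STAT5 model.
#
# Units: nM and hours.  Second-order constants nM^-1 h^-1 (kfR41 is third
# order, nM^-2 h^-1), first-order h^-1, V_transc nM h^-1, K_transc nM,
# n_transc dimensionless.  Magnitudes for the canonical core follow the
# published JAK-STAT literature models; the heterodimerization and s80
# constants are calibrated so the combined model reproduces the observed
# early antagonism / late agonism of beta-casein expression under NRG and
# the ~3 h STAT5->mRNA delay at tenfold-reduced mRNA export.
compartments:
  cyt: 1.0
  nuc: 0.25

parameters:
  kfR01: 0.1        # HER4 JAK Binding
  krR01: 0.5        # HER4 JAK Unbinding
  kfR02: 0.5        # NRG HER4 JAK Binding
  kR03: 10.0        # HER4 JAK Activation
  kR05: 0.01        # Receptor Dephosphorylation SHP
  kR06: 0.01        # STATc Phosphorylation JAK Dependent
  kR08: 0.02        # STATc Dephosphorylation PPX
  kR12: 0.02        # STAT Dimerization
  kR15: 1.0         # STAT Dimer Nuclear Translocation
  kfR19: 0.02       # Nuclear STAT Dimer PPN Binding
  kR20: 0.5         # Nuclear STAT dimer dephosphorylation
  kR21: 0.5         # STAT Nuclear Export
  V_transc: 40.0    # Transcription Half-Maximum rate (Hill Vmax)
  K_transc: 100.0   # Transcription Equilibrium Coefficient
  n_transc: 2.0     # Transcription Hill Coefficient
  kR24: 1.0         # mRNA Nuclear Export (SOCS)
  kR25: 1.0         # Translation
  kR26: 0.2         # SOCS mRNA Degradation
  kR27: 0.1         # SOCS Degradation
  SOCS_Binding_Rate: 0.2   # SOCS Mediated negative feedback
  kfR29: 0.2       # STATc SOCS HER4 JAK SHP Binding
  kR30: 1.0         # SOCS Complex Dissociation
  kR45: 8.0         # mRNA Nuclear Export Casein
  kR46: 0.5         # mRNA degradation rate (casein)
  kR47: 0.5         # Casein Translation
  k_basal_cas: 1.0  # Basal (HC/GR-driven) casein transcription, nM/h
  kfR41: 0.01       # HER4 Heterodimerization (ligand-dependent, third order)
  krR41: 1.0        # HER4 Heterodimer (ligand-bound) Dissociation
  kfR42: 0.001      # HER4 Heterodimerization Constitutive
  krR42: 1.0        # HER4 Heterodimer Dissociation
  kfR43: 0.5        # HER4 Heterodimer Ligand Binding
  krR43: 1.0        # HER4 Heterodimer Ligand Unbinding
  kfR36: 0.015      # IFNR (HER4 s80) Formation
  kR37: 0.05        # IFNR (HER4 s80) Activation
  kR39: 0.005       # STATc Phosphorylation JAK independent (0.5 * kR06)

initial_amounts:
  NRG: 0.0          # set by the dose protocol
  HER4: 100.0
  JAK: 50.0
  ERBB: 120.0       # lumped HER2+HER3 partner pool
  STATc: 200.0
  SHP: 50.0
  PPX: 50.0
  PPN: 60.0
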