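# Chemistry tables for lipid identification.
#
# atomic_masses: IUPAC monoisotopic atomic masses (Da), >= 6 decimal places.
# classes: per-class elemental base formula at the (0:0) reference sum
#   composition. A species formula is base + carbons*CH2 - double_bonds*H2
#   + hydroxyls*O. Bases were derived from the structural chemistry of each
#   class (glycerol/long-chain-base + acyls + headgroup, minus waters of
#   esterification) and validated against reference compounds.
# adducts: ionization adducts; mass_delta includes the electron mass.

atomic_masses:
  H: 1.00782503207
  D: 2.01410177812
  C: 12.0
  N: 14.0030740048
  O: 15.9949146196
  P: 30.97376163
  S: 31.97207100
  Na: 22.9897692809
  K: 38.96370668
  Cl: 34.96885268

electron_mass: 0.00054857990907

classes:
  PC:   {base: {C: 8,  H: 16, N: 1, O: 8,  P: 1}, polarity: positive, polar: true,  n_chains: 2}
  LPC:  {base: {C: 8,  H: 18, N: 1, O: 7,  P: 1}, polarity: positive, polar: true,  n_chains: 1}
  PE:   {base: {C: 5,  H: 10, N: 1, O: 8,  P: 1}, polarity: negative, polar: true,  n_chains: 2}
  LPE:  {base: {C: 5,  H: 12, N: 1, O: 7,  P: 1}, polarity: negative, polar: true,  n_chains: 1}
  MMPE: {base: {C: 6,  H: 12, N: 1, O: 8,  P: 1}, polarity: negative, polar: true,  n_chains: 2}
  DMPE: {base: {C: 7,  H: 14, N: 1, O: 8,  P: 1}, polarity: negative, polar: true,  n_chains: 2}
  PI:   {base: {C: 9,  H: 15, O: 13, P: 1},       polarity: negative, polar: true,  n_chains: 2}
  LPI:  {base: {C: 9,  H: 17, O: 12, P: 1},       polarity: negative, polar: true,  n_chains: 1}
  PS:   {base: {C: 6,  H: 10, N: 1, O: 10, P: 1}, polarity: negative, polar: true,  n_chains: 2}
  LPS:  {base: {C: 6,  H: 12, N: 1, O: 9,  P: 1}, polarity: negative, polar: true,  n_chains: 1}
  PA:   {base: {C: 3,  H: 5,  O: 8,  P: 1},       polarity: negative, polar: true,  n_chains: 2}
  PG:   {base: {C: 6,  H: 11, O: 10, P: 1},       polarity: negative, polar: true,  n_chains: 2}
  CL:   {base: {C: 9,  H: 14, O: 17, P: 2},       polarity: negative, polar: true,  n_chains: 4}
  Cer:  {base: {H: 1,  N: 1,  O: 1},              polarity: negative, polar: true,  n_chains: 2, sphingo: true}
  IPC:  {base: {C: 6,  H: 12, N: 1, O: 9,  P: 1}, polarity: negative, polar: true,  n_chains: 2, sphingo: true}
  MIPC: {base: {C: 12, H: 22, N: 1, O: 14, P: 1}, polarity: negative, polar: true,  n_chains: 2, sphingo: true}
  DG:   {base: {C: 3,  H: 4,  O: 5},              polarity: positive, polar: false, n_chains: 2}
  TG:   {base: {C: 3,  H: 2,  O: 6},              polarity: positive, polar: false, n_chains: 3}
  EE:   {base: {C: 28, H: 42, O: 2},              polarity: positive, polar: false, n_chains: 1}

adducts:
  "[M+H]+":   {polarity: positive, mass_delta: 1.00727645, charge: 1}
  "[M+NH4]+": {polarity: positive, mass_delta: 18.03382555, charge: 1}
  "[M-H]-":   {polarity: negative, mass_delta: -1.00727645, charge: -1}
  "[M+Cl]-":  {polarity: negative, mass_delta: 34.96940126, charge: -1}
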