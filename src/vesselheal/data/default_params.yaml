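# Default parameter registry for the arterial clamping/healing simulator.
#
# Keys follow the symbols conventional in the constrained-mixture and
# smooth-muscle-contraction literature.  Each entry carries a value, its
# unit (dimensionless entries use "-") and a provenance code:
#   1 exact literature value, 2 representative literature value,
#   3 manually fitted, 4 fitted within a literature order of magnitude,
#   5 estimated.
initial_densities:
  rho0elas:  {value: 0.35, units: "-", provenance: 2}
  rho0coll:  {value: 0.30, units: "-", provenance: 2}
  rho0csmc:  {value: 0.30, units: "-", provenance: 2}
  rho0ssmc:  {value: 0.05, units: "-", provenance: 2}
passive:
  C10:    {value: 0.04, units: MPa, provenance: 2}
  k1:     {value: 1.0,  units: MPa, provenance: 2}
  k2:     {value: 1.5,  units: "-", provenance: 2}
  kappa:  {value: 0.1,  units: "-", provenance: 5}
  alpha:  {value: 0.39269908169872414, units: rad, provenance: 5}  # pi/8
smc:
  mucsmc: {value: 0.42, units: MPa, provenance: 4}
  kappac: {value: 1.55, units: MPa, provenance: 4}
prestretch:
  gax:   {value: 1.67, units: "-", provenance: 1}
  gcoll: {value: 1.1,  units: "-", provenance: 2}
damage:
  mcsmc: {value: 1.0,  units: "-", provenance: 3}
  mcoll: {value: 20.0, units: "-", provenance: 3}
  mec:   {value: 0.38, units: "-", provenance: 3}
remodeling:
  Kqhcoll: {value: 0.006931471805599453, units: 1/day, provenance: 3}  # ln(2)/100
  Kmcoll:  {value: 26.64, units: "-",    provenance: 3}
  Kplsmc:  {value: 4.0,   units: 1/day,  provenance: 3}
  Kec:     {value: 0.08,  units: 1/day,  provenance: 3}
  Kddsmc:  {value: 1.6,   units: 1/day,  provenance: 3}
  Kicsmc:  {value: 0.01,  units: 1/day,  provenance: 3}
contractility:
  k3:     {value: 0.4,  units: 1/s, provenance: 1}
  k4:     {value: 0.1,  units: 1/s, provenance: 1}
  k7:     {value: 0.01, units: 1/s, provenance: 1}
  k2hom:  {value: 0.5,  units: 1/s, provenance: 1}
  alpha2: {value: 0.1,  units: 1/s, provenance: 3}
  eta:    {value: 60.0, units: MPa*s, provenance: 1}
  KNO:     {value: 8.0e-8,  units: M, provenance: 3}
  KPE:     {value: 2.0e-7,  units: M, provenance: 3}
  Cahom:   {value: 2.7e-7,  units: M, provenance: 2}
  alphaNO: {value: 1.4e-7,  units: M, provenance: 3}
  alphaPE: {value: 1.28e-7, units: M, provenance: 3}
  alphaCa: {value: 0.24,    units: "-", provenance: 3}
  KCaCaM:  {value: 1.78e-7, units: M, provenance: 1}
  # log-linear saturation of endothelial NO release vs ACh concentration
  ach_no_amplitude: {value: 2.8e-7, units: M,   provenance: 2}
  ach_no_offset:    {value: 8.2,    units: "-", provenance: 2}
  ach_no_shape:     {value: 0.9,    units: "-", provenance: 2}
geometry:
  inner_diameter: {value: 0.65, units: mm,  provenance: 2}
  thickness:      {value: 0.04, units: mm,  provenance: 2}
  segment_length: {value: 0.04, units: mm,  provenance: 2}
  pressure:       {value: 0.01, units: MPa, provenance: 1}  # 10 kPa diastolic
myograph:
  rod_radius:         {value: 0.15,   units: mm,   provenance: 1}
  preload_per_length: {value: 0.0133, units: N/mm, provenance: 1}
numerics:
  dt_day: {value: 1.0,  units: day, provenance: 1}
  dt_s:   {value: 0.01, units: s,   provenance: 5}
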