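# Parameter file schema

`GatingParameters.from_yaml` / `.to_yaml` read and write a YAML mapping
whose keys mirror the `GatingParameters` fields.  All voltages are in
millivolts, all rates in s⁻¹, temperatures in kelvin.

```yaml
vsd_rates:            # intrinsic VSD rate laws, k(V) = k0 * exp(z F V / R T)
  ri: {k0: 35.0, z: 0.8}     # resting -> intermediate; k0 in 1/s at 0 mV,
  ir: {k0: 1.5,  z: -0.8}    # z in elementary charges (signed)
  ia: {k0: 2.0,  z: 0.7}
  ai: {k0: 7.8,  z: -0.7}
k_co: 6.0             # intrinsic pore opening rate, 1/s, voltage-independent
k_oc: 300.0           # intrinsic pore closing rate, 1/s
theta_rc: 1.0         # VSD-pore coupling strengths, dimensionless, > 0;
theta_ic: 1.0         #   theta_XP > 1 stabilizes the (X, P) pair and slows
theta_ac: 1.0         #   every transition leaving it
theta_ro: 1.0
theta_io: 2.3
theta_ao: 2.7
n_channels: 1000.0    # channel count N (current scale)
ions:                 # per ion condition: max conductance (arbitrary units)
  K:  {g: 1.0,  e_rev_mv: -80.0}   # and reversal potential (mV)
  Rb: {g: 0.7,  e_rev_mv: -80.0}
  Na: {g: 0.05, e_rev_mv: -80.0}
f_i: 0.8              # relative fluorescence of an intermediate-state VSD
f_a: 1.0              # ... of an activated-state VSD (resting = 0; f_a >= f_i)
constants:            # physical constants
  F: 96485.332        # C/mol
  R: 8.31446          # J/(mol K)
  T: 298.15           # K
```

Protocol files (`VoltageProtocol.from_yaml`) are:

```yaml
segments:             # ordered [duration_ms, voltage_mv] pairs
  - [4000.0, 0.0]
  - [1000.0, 60.0]
sample_interval_ms: 1.0    # must divide every segment boundary
holding_voltage_mv: -80.0
```
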