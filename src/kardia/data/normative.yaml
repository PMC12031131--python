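# Short-term (~5 min) HRV normative limits used by the composite HRV grade.
#
# sdnn / rmssd lower-upper: 95% normal ranges for healthy adults from the
# systematic review of short-term HRV norms (Nunan, Sandercock & Brodie 2010,
# as tabulated in Shaffer & Ginsberg 2017).  total_power: no pooled
# short-term norm is published at the same level of evidence; the packaged
# lower limit is a package-derived approximation (order of the summed lower
# band norms) and is expected to be overridden with site-specific values.
# Units: sdnn, rmssd in ms; total_power in ms^2.  Values equal to a limit
# count as normal.
sdnn:
  lower: 32.0
  upper: 93.0
  units: ms
  source: "Nunan et al. 2010 short-term norms (via Shaffer & Ginsberg 2017)"
rmssd:
  lower: 19.0
  upper: 75.0
  units: ms
  source: "Nunan et al. 2010 short-term norms (via Shaffer & Ginsberg 2017)"
total_power:
  lower: 500.0
  upper: null
  units: ms^2
  source: "package approximation (sum of lower band norms); override recommended"
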