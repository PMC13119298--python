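# Editable stand-in modulation table: uniformly spaced transverse
# polarizations with a +/-20 deg sheet-tilt spread per view.
# Not the published acquisition table.
- view: A
  pol_deg: 0.0
  tilt_deg: -20.0
- view: A
  pol_deg: 60.0
  tilt_deg: 0.0
- view: A
  pol_deg: 120.0
  tilt_deg: 20.0
- view: B
  pol_deg: 0.0
  tilt_deg: -20.0
- view: B
  pol_deg: 60.0
  tilt_deg: 0.0
- view: B
  pol_deg: 120.0
  tilt_deg: 20.0
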