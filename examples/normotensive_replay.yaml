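# A typical trabecula replaying a recorded-style 3.5 mN isometric twitch
# against the healthy-rat arterial impedance at 1 Hz.
geometry:
  L0_mm: 1.8
  diameter_mm: 0.26
windkessel:
  preset: normotensive
cycle:
  stim_hz: 1.0
muscle:
  mode: replay
  twitch_peak_mN: 3.5
  twitch_rise_ms: 40
  twitch_fall_ms: 120
sim:
  mode: windkessel
  duration_s: 12.0
  decimation: 10
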