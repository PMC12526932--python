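# Nominal profile; see pixel_2_xl.yaml for provenance notes.
name: galaxy_a20e
accel_rate_hz: 100.0
touch_rate_hz: 120.0
audio_latency_ms: [60.0, 12.0]
vib_latency_ms: [15.0, 8.0]
touch_pipeline_latency_ms: [20.0, 5.0]
accel_noise_sd: 0.08
has_low_latency: false
has_pro: false
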