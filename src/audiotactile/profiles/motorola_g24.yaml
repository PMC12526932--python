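# Nominal profile; see pixel_2_xl.yaml for provenance notes.
name: motorola_g24
accel_rate_hz: 410.0
touch_rate_hz: 90.0
audio_latency_ms: [55.0, 10.0]
vib_latency_ms: [12.0, 3.0]
touch_pipeline_latency_ms: [18.0, 4.0]
accel_noise_sd: 0.06
has_low_latency: true
has_pro: false
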