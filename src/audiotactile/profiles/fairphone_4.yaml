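# Nominal profile; see pixel_2_xl.yaml for provenance notes.
name: fairphone_4
accel_rate_hz: 410.0
touch_rate_hz: 60.0
audio_latency_ms: [30.0, 3.0]
vib_latency_ms: [10.0, 3.0]
touch_pipeline_latency_ms: [16.0, 3.0]
accel_noise_sd: 0.05
has_low_latency: true
has_pro: true
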