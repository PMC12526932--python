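# Nominal profile. Sensor rates, round-trip audio latency (30 ms -> 15 ms
# one-way) and feature flags are declared device figures; latency SDs and
# vibration/touch-pipeline latencies are synthetic nominal values.
name: pixel_2_xl
accel_rate_hz: 500.0
touch_rate_hz: 120.0
audio_latency_ms: [15.0, 2.0]
vib_latency_ms: [10.0, 3.0]
touch_pipeline_latency_ms: [15.0, 3.0]
accel_noise_sd: 0.05
has_low_latency: true
has_pro: true
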