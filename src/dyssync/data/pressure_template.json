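{
  "description": "Normalized LV pressure reference waveform, piecewise-cosine. Landmarks are expressed as fractions of the peak systolic amplitude; the waveform is time-warped so that its landmark points coincide with the valve events (MVC, AVO, AVC, MVO) of a given cycle and amplitude-scaled so its maximum equals the systolic blood pressure.",
  "diastolic_mmHg": 5.0,
  "aortic_opening_frac": 0.65,
  "aortic_closure_frac": 0.45,
  "peak_position_frac": 0.4
}
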