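# Annotated simulation config for `lipidrhythm simulate` / `lipidrhythm run-all`.
# All concentrations in mg/dL, all clock values in local hours.

n_participants: 13

# Device imprecision: multiplicative Gaussian noise, percent coefficient
# of variation of a single measurement.
measurement_cv: 4.15

# Population baselines: per-analyte mean and between-person SD.
baselines:
  TC:  {mean: 185.0, sd: 25.0}
  HDL: {mean: 55.0,  sd: 12.0}
  TG:  {mean: 150.0, sd: 60.0}

# Daily (circadian-range) multiplicative cosines. relative_amplitude A gives
# a percent-of-maximum fluctuation of 2A/(1+A); acrophase is the clock hour
# of the peak. HDL is arrhythmic (null).
daily:
  TC:  {period: 24.0, relative_amplitude: 0.25,       acrophase: 16.0}  # ~40% of max
  TG:  {period: 24.0, relative_amplitude: 0.20481928, acrophase: 16.0}  # ~34% of max
  HDL: null

# Individual daily acrophases are drawn around the population value.
acrophase_sd_h: 1.0

# Ultradian triglyceride pulses (~4 h period). Set to null to disable.
tg_ultradian: {period: 4.0, relative_amplitude: 0.15, acrophase: 14.0}

# Menstrual envelope on TC (additive rise-fall, mg/dL). null disables it.
# Example for a single-subject cycle experiment:
#   menstrual: {cycle_length: 28, peak_day: 14, range_mgdl: 50.0}
menstrual: null

# Postprandial TG bumps: additive step at each meal with exponential decay.
# gain 0 disables the term.
meal_times: [8.0, 13.0, 19.0]
postprandial_tg_gain: 0.0
postprandial_decay_h: 2.0

# Perceived-hunger phase relative to the TG ultradian component, radians.
# pi = antiphase (hungriest at the TG trough).
hunger_phase_offset: 3.141592653589793

# Sampling scheme. One of:
#   {scheme: within_day_serial, interval_h: 1.0, start_h: 6.0, end_h: 22.0, n_days: 1}
#   {scheme: across_mornings, window_start_h: 6.0, window_end_h: 8.0, n_days: 30}
#   {scheme: hourly_waking, start_h: 5.0, end_h: 24.0, n_days: 1}
sampling: {scheme: within_day_serial, interval_h: 1.0, start_h: 6.0, end_h: 22.0, n_days: 1}

seed: 0
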