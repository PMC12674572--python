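# Synthetic activity-profile set (stand-in for a full laboratory protocol).
#
# This is an EMULATION: a 12-condition default set spanning the eight
# superordinate activity categories, not a copy of any study's condition
# list. Amplitudes, fundamentals and between-person sigmas are chosen to
# reproduce the qualitative structure of multi-position accelerometry
# (jogging >> walking >> postures; wrist-dominant ADL; leg-dominant
# cycling; largest between-person spread for wrist-measured jogging),
# not to match any published table quantitatively. Users can extend the
# condition list to a full 32-entry protocol.
#
# Units: amplitude_mg and noise_sd_mg in milli-g; fundamental_hz in Hz;
# gravity vectors are unit 3-vectors (sensor orientation at rest);
# between_person_sigma is the lognormal sigma of the per-participant
# amplitude multiplier (median 1).

harmonics: {1: 1.0, 2: 0.4}

categories:
  lying:
    between_person_sigma: 0.05
    fundamental_hz: 0.3
    noise_sd_mg: 4.0
    gravity:
      default: [0.0, 0.0, 1.0]
    amplitude_mg:
      {thigh: 0.0, hip: 0.0, chest: 0.0, ankle: 0.0, wrist: 0.0, upper_arm: 0.0}
  sitting:
    between_person_sigma: 0.05
    fundamental_hz: 0.3
    noise_sd_mg: 4.0
    gravity:
      default: [0.0, 1.0, 0.0]
      thigh: [0.0, 0.0, 1.0]
    amplitude_mg:
      {thigh: 5.0, hip: 5.0, chest: 6.0, ankle: 5.0, wrist: 12.0, upper_arm: 8.0}
  standing:
    between_person_sigma: 0.15
    fundamental_hz: 0.5
    noise_sd_mg: 5.0
    gravity:
      default: [0.0, 1.0, 0.0]
    amplitude_mg:
      {thigh: 20.0, hip: 25.0, chest: 35.0, ankle: 12.0, wrist: 60.0, upper_arm: 40.0}
  adl:
    between_person_sigma: 0.25
    fundamental_hz: 0.8
    noise_sd_mg: 8.0
    gravity:
      default: [0.0, 1.0, 0.0]
    amplitude_mg:
      {thigh: 70.0, hip: 60.0, chest: 60.0, ankle: 90.0, wrist: 220.0, upper_arm: 120.0}
  climbing_stairs:
    between_person_sigma: 0.12
    fundamental_hz: 1.8
    noise_sd_mg: 10.0
    gravity:
      default: [0.0, 1.0, 0.0]
    amplitude_mg:
      {thigh: 450.0, hip: 380.0, chest: 380.0, ankle: 700.0, wrist: 380.0, upper_arm: 370.0}
  walking:
    between_person_sigma: 0.10
    fundamental_hz: 1.9
    noise_sd_mg: 10.0
    gravity:
      default: [0.0, 1.0, 0.0]
    amplitude_mg:
      {thigh: 430.0, hip: 290.0, chest: 260.0, ankle: 720.0, wrist: 260.0, upper_arm: 230.0}
  jogging:
    between_person_sigma: 0.25
    fundamental_hz: 2.8
    noise_sd_mg: 15.0
    gravity:
      default: [0.0, 1.0, 0.0]
    amplitude_mg:
      {thigh: 1250.0, hip: 1100.0, chest: 1150.0, ankle: 1600.0, wrist: 1350.0, upper_arm: 1100.0}
  cycling:
    between_person_sigma: 0.12
    fundamental_hz: 1.5
    noise_sd_mg: 8.0
    gravity:
      default: [0.0, 1.0, 0.0]
      thigh: [0.0, 0.7071067811865476, 0.7071067811865476]
    amplitude_mg:
      {thigh: 240.0, hip: 105.0, chest: 100.0, ankle: 380.0, wrist: 90.0, upper_arm: 110.0}

conditions:
  lying_horizontal:        {category: lying,           duration_s: 150, scale: 1.0}
  sitting_leaned_backwards: {category: sitting,        duration_s: 150, scale: 1.0}
  sitting_upright:         {category: sitting,         duration_s: 120, scale: 1.2}
  standing_still:          {category: standing,        duration_s: 120, scale: 1.0}
  tidying_up:              {category: adl,             duration_s: 240, scale: 1.0}
  hanging_out_laundry:     {category: adl,             duration_s: 240, scale: 1.3}
  climbing_stairs_up:      {category: climbing_stairs, duration_s: 120, scale: 1.0}
  walking_3.2kmh:          {category: walking,         duration_s: 180, scale: 0.7}
  walking_5.5kmh:          {category: walking,         duration_s: 180, scale: 1.2}
  jogging_8kmh:            {category: jogging,         duration_s: 180, scale: 1.0}
  jogging_10kmh:           {category: jogging,         duration_s: 150, scale: 1.2}
  cycling:                 {category: cycling,         duration_s: 300, scale: 1.0}
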