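# Default condition -> superordinate-category mapping (32 entries).
#
# The condition names are a configurable emulation of a structured
# laboratory protocol (fully standardized postures plus semi-standardized
# household and locomotion tasks); edit or replace this file to match your
# own protocol. Categories must be one of: lying, sitting, standing, adl,
# climbing_stairs, walking, jogging, cycling.

lying_horizontal: lying
lying_on_side: lying
lying_reading: lying

sitting_leaned_backwards: sitting
sitting_upright: sitting
sitting_reading_newspaper: sitting
sitting_working_on_computer: sitting
sitting_talking: sitting

standing_still: standing
standing_talking: standing
standing_leaning: standing
queuing_standing: standing

tidying_up: adl
hanging_out_laundry: adl
sweeping_floor: adl
setting_table: adl
carrying_boxes: adl
washing_dishes: adl
stretching: adl

climbing_stairs_up: climbing_stairs
climbing_stairs_down: climbing_stairs

walking_3.2kmh: walking
walking_4.3kmh: walking
walking_5.5kmh: walking
walking_6.5kmh: walking
nordic_walking: walking

jogging_8kmh: jogging
jogging_10kmh: jogging
jogging_12kmh: jogging

cycling: cycling
cycling_ergometer_low: cycling
cycling_ergometer_high: cycling
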