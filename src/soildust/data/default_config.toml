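# Default model configuration.
#
# [vars.*]  — input-variable distributions per age group.  Entries marked
#             note = "reconstructed" are documented stand-in defaults for
#             survey-based inputs that are not published; override them
#             from a user config for site-specific work.
# [diary.*] — parameters of the synthetic activity-diary generator.
#
# Distribution parameter conventions: point — value; uniform — min, max;
# normal — mean, SD; lognormal — geometric mean, geometric SD;
# beta — alpha, beta[, scale]; exponential — min, mean, max (bounded).

schema_version = 1

# ---------------------------------------------------------------- diary --

[diary]
wake_time_mean_min = 420
wake_time_sd_min = 30
weekend_outdoor_multiplier = 1.3
bath_min = 12
handwash_min = 2

[diary.age."0-<1m"]
sleep_h = 16.0
nap_min = 240
handwash_per_day = 1.0
baths_per_day = 1.0
outdoor_frac = { winter = 0.01, spring = 0.02, summer = 0.03, fall = 0.02 }

[diary.age."1-<3m"]
sleep_h = 15.5
nap_min = 240
handwash_per_day = 1.0
baths_per_day = 1.0
outdoor_frac = { winter = 0.01, spring = 0.02, summer = 0.03, fall = 0.02 }

[diary.age."3-<6m"]
sleep_h = 15.0
nap_min = 210
handwash_per_day = 1.5
baths_per_day = 1.0
outdoor_frac = { winter = 0.01, spring = 0.03, summer = 0.04, fall = 0.03 }

[diary.age."6m-<1y"]
sleep_h = 14.0
nap_min = 180
handwash_per_day = 2.0
baths_per_day = 1.0
outdoor_frac = { winter = 0.02, spring = 0.04, summer = 0.05, fall = 0.04 }

[diary.age."1-<2y"]
sleep_h = 13.0
nap_min = 120
handwash_per_day = 3.0
baths_per_day = 1.0
outdoor_frac = { winter = 0.03, spring = 0.07, summer = 0.10, fall = 0.07 }

[diary.age."2-<3y"]
sleep_h = 12.5
nap_min = 90
handwash_per_day = 3.0
baths_per_day = 1.0
outdoor_frac = { winter = 0.04, spring = 0.08, summer = 0.12, fall = 0.08 }

[diary.age."3-<6y"]
sleep_h = 11.5
nap_min = 45
handwash_per_day = 4.0
baths_per_day = 1.0
outdoor_frac = { winter = 0.04, spring = 0.09, summer = 0.13, fall = 0.09 }

[diary.age."6-<11y"]
sleep_h = 10.5
nap_min = 0
handwash_per_day = 4.0
baths_per_day = 1.0
outdoor_frac = { winter = 0.04, spring = 0.09, summer = 0.14, fall = 0.09 }

[diary.age."11-<16y"]
sleep_h = 9.5
nap_min = 0
handwash_per_day = 3.0
baths_per_day = 1.0
outdoor_frac = { winter = 0.03, spring = 0.07, summer = 0.11, fall = 0.07 }

[diary.age."16-<21y"]
sleep_h = 9.0
nap_min = 0
handwash_per_day = 3.0
baths_per_day = 1.0
outdoor_frac = { winter = 0.03, spring = 0.06, summer = 0.09, fall = 0.06 }

# ------------------------------------------- blanket / pacifier variables --

[vars.p_blanket]
units = "probability"
scope = "per_event"
default = { family = "point", params = [0.0] }

[vars.p_blanket.by_age]
"0-<1m" = { family = "uniform", params = [0.8, 1.0] }
"1-<3m" = { family = "uniform", params = [0.8, 1.0] }
"3-<6m" = { family = "uniform", params = [0.8, 1.0] }
"6m-<1y" = { family = "uniform", params = [0.0, 1.0] }
"1-<2y" = { family = "uniform", params = [0.0, 0.2] }

[vars.f_blanket]
units = "fraction"
scope = "per_person"
default = { family = "uniform", params = [0.1, 0.4] }

[vars.pacifier_size]
units = "cm^2"
scope = "per_person"
default = { family = "uniform", params = [8.0, 11.0] }

[vars.pacifier_frac_hard]
units = "fraction"
scope = "per_person"
default = { family = "point", params = [0.25] }

[vars.pacifier_frac_soft]
units = "fraction"
scope = "per_person"
default = { family = "uniform", params = [0.25, 0.5] }

[vars.pacifier_transfer]
units = "fraction/drop"
scope = "per_event"
default = { family = "uniform", params = [0.25, 0.75] }

[vars.pacifier_washing]
units = "fraction"
scope = "per_person"
default = { family = "point", params = [0.0] }

[vars.pacifier_drop]
units = "1/h"
scope = "per_person"
default = { family = "point", params = [0.0] }

[vars.pacifier_drop.by_age]
"0-<1m" = { family = "normal", params = [8.0, 3.0], truncation = [0.0, inf] }
"1-<3m" = { family = "normal", params = [8.0, 3.0], truncation = [0.0, inf] }
"3-<6m" = { family = "normal", params = [8.0, 3.0], truncation = [0.0, inf] }
"6m-<1y" = { family = "normal", params = [5.0, 2.0], truncation = [0.0, inf] }
"1-<2y" = { family = "normal", params = [2.0, 1.0], truncation = [0.0, inf] }

[vars.p_pacifier]
units = "probability"
scope = "per_event"
note = "1-<2y row reconstructed (occasional use)"
default = { family = "point", params = [0.0] }

[vars.p_pacifier.by_age]
"0-<1m" = { family = "uniform", params = [0.8, 1.0] }
"1-<3m" = { family = "uniform", params = [0.8, 1.0] }
"3-<6m" = { family = "uniform", params = [0.8, 1.0] }
"6m-<1y" = { family = "uniform", params = [0.5, 1.0] }
"1-<2y" = { family = "uniform", params = [0.0, 0.5] }

# -------------------------------------------------- age-dependent inputs --

[vars.adherence_soil]
units = "mg/cm^2"
scope = "per_person"
default = { family = "lognormal", params = [0.11, 2.0] }

[vars.adherence_soil.by_age]
"0-<1m" = { family = "point", params = [0.0] }
"1-<3m" = { family = "point", params = [0.0] }
"3-<6m" = { family = "point", params = [0.0] }
"6m-<1y" = { family = "point", params = [0.0] }
"1-<2y" = { family = "lognormal", params = [0.055, 2.0] }

[vars.hand_mouth_fraction]
units = "fraction of one hand's area"
scope = "per_person"
note = "reconstructed; 0.10 anchors on thumb-sucking"
default = { family = "point", params = [0.10] }

[vars.hand_mouth_fraction.by_age]
"6-<11y" = { family = "point", params = [0.08] }
"11-<16y" = { family = "point", params = [0.05] }
"16-<21y" = { family = "point", params = [0.03] }

[vars.hand_mouth_freq]
units = "contacts/h awake"
scope = "per_person"
note = "reconstructed"
default = { family = "normal", params = [12.0, 4.0], truncation = [0.0, inf] }

[vars.hand_mouth_freq.by_age]
"0-<1m" = { family = "normal", params = [10.0, 3.0], truncation = [0.0, inf] }
"1-<3m" = { family = "normal", params = [13.0, 4.0], truncation = [0.0, inf] }
"3-<6m" = { family = "normal", params = [16.0, 5.0], truncation = [0.0, inf] }
"6m-<1y" = { family = "normal", params = [18.0, 5.0], truncation = [0.0, inf] }
"1-<2y" = { family = "normal", params = [20.0, 6.0], truncation = [0.0, inf] }
"2-<3y" = { family = "normal", params = [16.0, 5.0], truncation = [0.0, inf] }
"3-<6y" = { family = "normal", params = [12.0, 4.0], truncation = [0.0, inf] }
"6-<11y" = { family = "normal", params = [6.0, 2.0], truncation = [0.0, inf] }
"11-<16y" = { family = "normal", params = [2.5, 1.0], truncation = [0.0, inf] }
"16-<21y" = { family = "normal", params = [1.5, 0.7], truncation = [0.0, inf] }

[vars.object_mouth_area]
units = "cm^2"
scope = "per_person"
note = "younger ages scaled by hand-size ratio (reconstructed)"
default = { family = "exponential", params = [1.0, 10.0, 50.0] }

[vars.object_mouth_area.by_age]
"0-<1m" = { family = "exponential", params = [0.4, 4.0, 20.0] }
"1-<3m" = { family = "exponential", params = [0.5, 4.0, 20.0] }
"3-<6m" = { family = "exponential", params = [0.5, 5.0, 25.0] }
"6m-<1y" = { family = "exponential", params = [0.6, 6.0, 30.0] }
"1-<2y" = { family = "exponential", params = [0.8, 8.0, 40.0] }
"2-<3y" = { family = "exponential", params = [1.0, 9.0, 45.0] }

[vars.object_mouth_freq_indoor]
units = "contacts/h awake"
scope = "per_person"
note = "reconstructed"
default = { family = "point", params = [0.0] }

[vars.object_mouth_freq_indoor.by_age]
"1-<3m" = { family = "normal", params = [2.0, 1.0], truncation = [0.0, inf] }
"3-<6m" = { family = "normal", params = [6.0, 2.0], truncation = [0.0, inf] }
"6m-<1y" = { family = "normal", params = [10.0, 3.0], truncation = [0.0, inf] }
"1-<2y" = { family = "normal", params = [14.0, 4.0], truncation = [0.0, inf] }
"2-<3y" = { family = "normal", params = [10.0, 3.0], truncation = [0.0, inf] }
"3-<6y" = { family = "normal", params = [6.0, 2.0], truncation = [0.0, inf] }
"6-<11y" = { family = "normal", params = [2.0, 1.0], truncation = [0.0, inf] }

[vars.object_mouth_freq_outdoor]
units = "contacts/h awake"
scope = "per_person"
note = "reconstructed"
default = { family = "point", params = [0.0] }

[vars.object_mouth_freq_outdoor.by_age]
"1-<3m" = { family = "normal", params = [1.0, 0.5], truncation = [0.0, inf] }
"3-<6m" = { family = "normal", params = [3.0, 1.0], truncation = [0.0, inf] }
"6m-<1y" = { family = "normal", params = [6.0, 2.0], truncation = [0.0, inf] }
"1-<2y" = { family = "normal", params = [9.0, 3.0], truncation = [0.0, inf] }
"2-<3y" = { family = "normal", params = [7.0, 2.0], truncation = [0.0, inf] }
"3-<6y" = { family = "normal", params = [4.0, 1.5], truncation = [0.0, inf] }
"6-<11y" = { family = "normal", params = [1.5, 0.7], truncation = [0.0, inf] }

[vars.hand_surface_area]
units = "cm^2 (one hand)"
scope = "per_person"
note = "reconstructed"
default = { family = "normal", params = [135.0, 14.0], truncation = [0.0, inf] }

[vars.hand_surface_area.by_age]
"0-<1m" = { family = "normal", params = [60.0, 6.0], truncation = [0.0, inf] }
"1-<3m" = { family = "normal", params = [65.0, 7.0], truncation = [0.0, inf] }
"3-<6m" = { family = "normal", params = [75.0, 8.0], truncation = [0.0, inf] }
"6m-<1y" = { family = "normal", params = [85.0, 9.0], truncation = [0.0, inf] }
"1-<2y" = { family = "normal", params = [100.0, 10.0], truncation = [0.0, inf] }
"2-<3y" = { family = "normal", params = [115.0, 12.0], truncation = [0.0, inf] }
"6-<11y" = { family = "normal", params = [170.0, 17.0], truncation = [0.0, inf] }
"11-<16y" = { family = "normal", params = [210.0, 21.0], truncation = [0.0, inf] }
"16-<21y" = { family = "normal", params = [230.0, 23.0], truncation = [0.0, inf] }

# ---------------------------------------------------- home / dust inputs --

[vars.dust_home_soft]
units = "ug/cm^2"
scope = "per_person"
note = "reconstructed; ~4-fold above hard floor"
default = { family = "lognormal", params = [10.0, 3.0] }

[vars.dust_home_hard]
units = "ug/cm^2"
scope = "per_person"
note = "reconstructed"
default = { family = "lognormal", params = [2.5, 3.0] }

[vars.dust_object]
units = "ug/cm^2"
scope = "per_person"
note = "reconstructed"
default = { family = "lognormal", params = [2.5, 3.0] }

[vars.p_home_soft]
units = "probability"
scope = "per_event"
default = { family = "point", params = [0.5] }

[vars.dust_transfer_hand]
units = "fraction"
scope = "per_person"
note = "reconstructed"
default = { family = "uniform", params = [0.1, 0.3] }

[vars.saliva_removal]
units = "fraction"
scope = "per_person"
note = "reconstructed"
default = { family = "uniform", params = [0.3, 0.7] }

[vars.handwash_removal]
units = "fraction"
scope = "per_person"
note = "reconstructed"
default = { family = "uniform", params = [0.5, 0.9] }

[vars.bath_removal]
units = "fraction"
scope = "per_person"
note = "reconstructed"
default = { family = "uniform", params = [0.8, 1.0] }

[vars.hand_contact_fraction]
units = "fraction of hand area per contact"
scope = "per_person"
note = "reconstructed"
default = { family = "uniform", params = [0.1, 0.25] }
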