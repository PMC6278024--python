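# cataractflow service configuration — synthetic stand-in parameter set.
# ALL values are ASSUMED placeholders (the real service's parameter list is
# unpublished); they are calibrated so the baseline year lands at the scale
# of the published annual totals.  Rates are per week, durations in minutes,
# money in GBP.

# Referral demand (ASSUMED: a little above what the largest list can clear)
referral_rate_optometrist: 133.0
referral_rate_internal: 20.0

# Eye-examination outcomes: not_suitable, listed_direct, preop_clinic, preop_phone
exam_outcome_probs:
- 0.12
- 0.4
- 0.23
- 0.25

# Day-of-surgery behaviour (ASSUMED; elderly no-show rate > other by design)
p_unfit_on_day: 0.04
p_noshow_elderly: 0.08
p_noshow_other: 0.03
p_elderly: 0.65

# Anaesthesia, recovery routing and overnight stay
p_general_anaesthesia: 0.05
p_bed_local_elderly: 0.35
p_overnight: 0.01

# Activity durations (minutes; surgery centred on 20 min)
durations:
  eye_exam:
    family: lognormal
    mean: 32.0
    sd: 8.0
  preop_clinic:
    family: lognormal
    mean: 40.0
    sd: 9.0
  preop_phone:
    family: lognormal
    mean: 20.0
    sd: 5.0
  presurgery_tests:
    family: lognormal
    mean: 32.0
    sd: 7.0
  anaesthesia_local:
    family: triangular
    low: 3.0
    mode: 5.0
    high: 8.0
  anaesthesia_general:
    family: triangular
    low: 10.0
    mode: 15.0
    high: 25.0
  surgery:
    family: lognormal
    mean: 20.0
    sd: 5.0
  recovery_chair:
    family: lognormal
    mean: 45.0
    sd: 10.0
  recovery_bed:
    family: lognormal
    mean: 120.0
    sd: 25.0

# Theatre capacity (ASSUMED: the real theatres x lists/week split is unpublished)
theatres: 2
lists_per_theatre_per_week: 10
patients_per_list: 6

# Other resources (ASSUMED counts)
consult_rooms: 3
presurgery_rooms: 4
recovery_chairs: 4
recovery_beds: 2
doctors: 4
nurses: 8

# National-tariff revenue per activity and fully-absorbed staff cost rates
# (ASSUMED placeholders, not the real tariff schedule)
tariff_surgery: 700.0
tariff_first_appointment: 25.0
tariff_followup: 18.0
tariff_preop_clinic: 10.0
hourly_cost_doctor: 330.0
hourly_cost_nurse: 95.0
cost_per_surgery_other: 0.0

# Timetable and run shape
session_minutes: 240.0
working_days_per_week: 5
weeks_per_year: 52
warmup_weeks: 6
booking_lead_days: 7.0

# Rebooking after a lost slot
unfit_reschedule_delay_weeks: 2.0
p_noshow_rebooked: 0.8
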