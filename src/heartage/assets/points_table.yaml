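# Heart-age points table and atherogenic-index thresholds, version 1.
#
# Each band is [lower, upper, points] on a half-open interval [lower, upper);
# null bounds mean 0 / +infinity.  Printed integer bands like "130-145 / 146-160"
# are normalized to [130, 146) / [146, 161) so that non-integer laboratory
# values are always covered; the printed gap "200-239 / >240" becomes
# [200, 240) / [240, inf).  Blood pressure is banded per pressure (systolic and
# diastolic each against their own thresholds) and the scorer takes the
# higher-points band of the two.  treated_points is the override returned for
# glucose or blood pressure when the individual is under treatment for that
# factor, regardless of the measured value.
version: 1
male:
  total_chol:
    bands:
      - [null, 130, -5]
      - [130, 146, -4]
      - [146, 161, -3]
      - [161, 176, -2]
      - [176, 191, -1]
      - [191, 200, 0]
      - [200, 240, 1]
      - [240, null, 2]
  hdl:
    bands:
      - [null, 35, 2]
      - [35, 40, 1]
      - [40, 46, 0]
      - [46, 51, -1]
      - [51, 56, -2]
      - [56, 61, -3]
      - [61, 66, -4]
      - [66, null, -5]
  glucose:
    bands:
      - [null, 70, -5]
      - [70, 81, -3]
      - [81, 91, -2]
      - [91, 100, 0]
      - [100, 110, 2]
      - [110, 126, 3]
      - [126, null, 5]
    treated_points: 5
  smoker:
    "yes": 5
    "no": 0
  bmi:
    bands:
      - [null, 20, -2]
      - [20, 22.6, -1]
      - [22.6, 25, 0]
      - [25, 30, 1]
      - [30, 35, 2]
      - [35, null, 3]
  bp:
    sbp_bands:
      - [null, 120, -3]
      - [120, 140, 0]
      - [140, 160, 2]
      - [160, null, 3]
    dbp_bands:
      - [null, 80, -3]
      - [80, 90, 0]
      - [90, 100, 2]
      - [100, null, 3]
    treated_points: 3
female:
  total_chol:
    bands:
      - [null, 130, -5]
      - [130, 146, -4]
      - [146, 161, -3]
      - [161, 176, -2]
      - [176, 191, -1]
      - [191, 200, 0]
      - [200, 240, 1]
      - [240, null, 2]
  hdl:
    # The printed table's last row reads "<75 -5"; encoded as the >75 band so
    # the ladder is complete and ascending, mirroring the men's column.
    bands:
      - [null, 40, 2]
      - [40, 50, 1]
      - [50, 56, 0]
      - [56, 61, -1]
      - [61, 66, -2]
      - [66, 71, -3]
      - [71, 76, -4]
      - [76, null, -5]
  glucose:
    bands:
      - [null, 70, -5]
      - [70, 81, -3]
      - [81, 91, -2]
      - [91, 100, 0]
      - [100, 110, 2]
      - [110, 126, 3]
      - [126, null, 5]
    treated_points: 5
  smoker:
    "yes": 5
    "no": 0
  bmi:
    bands:
      - [null, 20, -2]
      - [20, 22.6, -1]
      - [22.6, 25, 0]
      - [25, 30, 1]
      - [30, 35, 2]
      - [35, null, 3]
  bp:
    sbp_bands:
      - [null, 120, -3]
      - [120, 140, 0]
      - [140, 160, 2]
      - [160, null, 3]
    dbp_bands:
      - [null, 80, -3]
      - [80, 90, 0]
      - [90, 100, 2]
      - [100, null, 3]
    treated_points: 3

# Clamp on the summed points: heart age = chronological age + clamp(sum, -20, +19).
clamp:
  lower: -20
  upper: 19

# High "avoidable lost life years" heart age: ALLY = HA - CA >= 17 years.
high_ally_cutoff: 17

# Atherogenic-index risk thresholds (unitless ratios).
atherogenic_thresholds:
  tc_hdl:
    female: {low_below: 4.5, high_above: 7.0}
    male: {low_below: 5.0, high_above: 9.0}
  ldl_hdl: {high_at_or_above: 3.0}
  tg_hdl: {high_at_or_above: 3.0}

# Friedewald LDL is unreliable above this triglyceride level (mg/dL).
friedewald_tg_max: 400.0
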