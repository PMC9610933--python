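# Simulated bolus schedules for the nine validation regimens, exactly as
# run in the validation (study totals redistributed by the dosing rules,
# then hand-adjusted; see docs/methods.md).  Times are minutes from
# simulation start; induction spans the first 3 min; simulation ends at
# 60 min.  Reference patient: female, 170 cm, 65 kg, ASA 2.
reference_patient:
  sex: female
  height_cm: 170
  weight_kg: 65
  asa: 2
  age_y: 40
regimens:
  - id: "1"
    T_p: 25
    induction: 3
    horizon: 60
    boluses:
      - {drug: midazolam, amount: 2.5, unit: mg, time: 0}
      - {drug: fentanyl, amount: 78, unit: ug, time: 0}
      - {drug: propofol, amount: 30, unit: mg, time: 0}
      - {drug: propofol, amount: 30, unit: mg, time: 2}
      - {drug: propofol, amount: 30, unit: mg, time: 4}
      - {drug: propofol, amount: 30, unit: mg, time: 6}
      - {drug: propofol, amount: 30, unit: mg, time: 8}
      - {drug: propofol, amount: 30, unit: mg, time: 10}
      - {drug: propofol, amount: 30, unit: mg, time: 12}
      - {drug: propofol, amount: 30, unit: mg, time: 14}
      - {drug: propofol, amount: 30, unit: mg, time: 16}
  - id: "2"
    T_p: 25
    induction: 3
    horizon: 60
    boluses:
      - {drug: fentanyl, amount: 67, unit: ug, time: 0}
      - {drug: propofol, amount: 40, unit: mg, time: 0}
      - {drug: propofol, amount: 30, unit: mg, time: 2}
      - {drug: propofol, amount: 30, unit: mg, time: 5}
      - {drug: propofol, amount: 30, unit: mg, time: 8}
      - {drug: propofol, amount: 40, unit: mg, time: 11}
      - {drug: propofol, amount: 30, unit: mg, time: 14}
      - {drug: propofol, amount: 30, unit: mg, time: 17}
      - {drug: propofol, amount: 30, unit: mg, time: 20}
      - {drug: propofol, amount: 40, unit: mg, time: 23}
      - {drug: propofol, amount: 30, unit: mg, time: 26}
  - id: "3"
    T_p: 11
    induction: 3
    horizon: 60
    boluses:
      - {drug: midazolam, amount: 1, unit: mg, time: 0}
      - {drug: fentanyl, amount: 50, unit: ug, time: 0}
      - {drug: propofol, amount: 30, unit: mg, time: 0}
      - {drug: propofol, amount: 10, unit: mg, time: 6}
      - {drug: propofol, amount: 10, unit: mg, time: 11}
  - id: "4"
    T_p: 12
    induction: 3
    horizon: 60
    boluses:
      - {drug: midazolam, amount: 3, unit: mg, time: 0}
      - {drug: fentanyl, amount: 100, unit: ug, time: 0}
  - id: "5"
    T_p: 8
    induction: 3
    horizon: 60
    boluses:
      - {drug: midazolam, amount: 3, unit: mg, time: 0}
      - {drug: alfentanil, amount: 600, unit: ug, time: 0}
      - {drug: propofol, amount: 10, unit: mg, time: 0}
  - id: "6"
    T_p: 22
    induction: 3
    horizon: 60
    boluses:
      - {drug: midazolam, amount: 3.8, unit: mg, time: 0}
      - {drug: alfentanil, amount: 400, unit: ug, time: 0}
      - {drug: alfentanil, amount: 400, unit: ug, time: 10}
      - {drug: propofol, amount: 10, unit: mg, time: 2}
      - {drug: propofol, amount: 10, unit: mg, time: 11}
  - id: "7"
    T_p: 25
    induction: 3
    horizon: 60
    boluses:
      - {drug: midazolam, amount: 1.1, unit: mg, time: 0}
      - {drug: fentanyl, amount: 52.5, unit: ug, time: 0}
      - {drug: propofol, amount: 20, unit: mg, time: 0}
      - {drug: propofol, amount: 20, unit: mg, time: 2}
      - {drug: propofol, amount: 20, unit: mg, time: 5}
      - {drug: propofol, amount: 20, unit: mg, time: 8}
      - {drug: propofol, amount: 20, unit: mg, time: 11}
      - {drug: propofol, amount: 20, unit: mg, time: 14}
      - {drug: propofol, amount: 20, unit: mg, time: 17}
      - {drug: propofol, amount: 20, unit: mg, time: 20}
  - id: "8"
    T_p: 16
    induction: 3
    horizon: 60
    boluses:
      - {drug: midazolam, amount: 1, unit: mg, time: 0}
      - {drug: fentanyl, amount: 50, unit: ug, time: 0}
      - {drug: propofol, amount: 30, unit: mg, time: 0}
      - {drug: propofol, amount: 20, unit: mg, time: 6}
      - {drug: propofol, amount: 30, unit: mg, time: 12}
  - id: "9"
    T_p: 28
    induction: 3
    horizon: 60
    boluses:
      - {drug: midazolam, amount: 3.25, unit: mg, time: 0}
      - {drug: fentanyl, amount: 50, unit: ug, time: 0}
      - {drug: propofol, amount: 20, unit: mg, time: 0}
      - {drug: propofol, amount: 30, unit: mg, time: 3}
      - {drug: propofol, amount: 20, unit: mg, time: 8}
      - {drug: propofol, amount: 20, unit: mg, time: 13}
      - {drug: propofol, amount: 20, unit: mg, time: 18}
      - {drug: propofol, amount: 20, unit: mg, time: 23}
      - {drug: propofol, amount: 15, unit: mg, time: 28}
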