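# Follow-up and treatment advice by severity category, editable clinical
# policy (derived from glaucoma management guidelines at the granularity of
# the grading scale). months_min/months_max bound the recommended interval.
categories:
  1:
    follow_up: "12 months"
    months_min: 12
    months_max: 12
    advice: "Clear field: routine annual review; repeat perimetry at the next visit."
  2:
    follow_up: "6 months"
    months_min: 6
    months_max: 6
    advice: "Mild defect: 6-monthly review; confirm defect reproducibility and optimise IOP control."
  3:
    follow_up: "3-6 months"
    months_min: 3
    months_max: 6
    advice: "Moderate defect: review every 3-6 months; reassess target IOP and consider treatment escalation."
  4:
    follow_up: "1-3 months"
    months_min: 1
    months_max: 3
    advice: "Severe defect: review every 1-3 months; intensive IOP lowering, consider surgical options."
  5:
    follow_up: "1 month"
    months_min: 1
    months_max: 1
    advice: "Diffuse defect / near-total loss: monthly review; maximal therapy, surgery with pharmacologic augmentation may be preferable, low-vision support."
progression:
  follow_up: "1-2 months"
  months_min: 1
  months_max: 2
  advice: "Progression detected: shorten follow-up to 1-2 months and escalate treatment review."
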