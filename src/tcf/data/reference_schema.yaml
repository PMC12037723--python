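# Reference schema: the 34 features retained by the selection pipeline on the
# development ICU cohort, plus the 28-day mortality outcome.  Kinds are
# declared, never inferred; units follow routine clinical reporting.
- {name: Age, kind: continuous, units: years, role: feature}
- {name: SH, kind: boolean, units: '', role: feature}          # surgical history
- {name: Temp, kind: continuous, units: degC, role: feature}
- {name: DBP, kind: continuous, units: mmHg, role: feature}    # diastolic blood pressure
- {name: LOC-ICU, kind: continuous, units: h, role: feature}   # length of ICU stay until discharge
- {name: OU, kind: continuous, units: L/min, role: feature}    # oxygen uptake
- {name: DOMV, kind: continuous, units: h, role: feature}      # duration of mechanical ventilation
- {name: hs-CRP, kind: continuous, units: mg/L, role: feature}
- {name: FBG, kind: continuous, units: g/L, role: feature}     # fibrinogen
- {name: PT, kind: continuous, units: s, role: feature}        # prothrombin time
- {name: APTT, kind: continuous, units: s, role: feature}
- {name: ALT, kind: continuous, units: IU/L, role: feature}
- {name: DBIL, kind: continuous, units: umol/L, role: feature} # direct bilirubin
- {name: Cr, kind: continuous, units: umol/L, role: feature}   # creatinine
- {name: UA, kind: continuous, units: umol/L, role: feature}   # uric acid
- {name: Tca, kind: continuous, units: mmol/L, role: feature}  # total calcium
- {name: K, kind: continuous, units: mmol/L, role: feature}
- {name: Na, kind: continuous, units: mmol/L, role: feature}
- {name: Lac, kind: continuous, units: mmol/L, role: feature}  # lactate
- {name: ALB, kind: continuous, units: g/L, role: feature}     # albumin
- {name: Glu, kind: continuous, units: mmol/L, role: feature}  # glucose
- {name: LYM, kind: continuous, units: 10^9/L, role: feature}  # lymphocyte count
- {name: WBC, kind: continuous, units: 10^9/L, role: feature}  # white blood cell count
- {name: Hb, kind: continuous, units: g/L, role: feature}      # haemoglobin
- {name: TC, kind: continuous, units: mmol/L, role: feature}   # total cholesterol
- {name: HDL-C, kind: continuous, units: mmol/L, role: feature}
- {name: MONO, kind: continuous, units: 10^9/L, role: feature} # monocyte count
- {name: PCT, kind: continuous, units: ng/mL, role: feature}   # procalcitonin
- {name: NOR, kind: continuous, units: count, role: feature}   # number of resuscitations
- {name: NOBP, kind: continuous, units: count, role: feature}  # number of blood purifications
- {name: NLR, kind: continuous, units: '', role: feature}
- {name: PLR, kind: continuous, units: '', role: feature}
- {name: LMR, kind: continuous, units: '', role: feature}
- {name: PAR, kind: continuous, units: '', role: feature}
- {name: death28, kind: boolean, units: '', role: outcome}     # all-cause death within 28 days
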