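# Plasma metabolite cutpoints (mmol/L) defining the fasting-phase decision
# regions.  Boundary convention: lower bounds inclusive, upper bounds
# exclusive.  The 0.3 mmol/L beta-HBA boundary is the field screening
# threshold; the BUN cutpoints are package defaults calibrated to the
# described concentration pattern and are fully configurable.
bhba_elevated: 0.3   # beta-HBA at/above this is "elevated" (ketotic)
bun_phase2_max: 5.0  # with elevated beta-HBA, BUN below this -> Phase II
bun_high: 9.0        # BUN at/above this is "high" (Phase III / Unclassified)
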