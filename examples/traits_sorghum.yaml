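# The 13 sorghum traits scored in the trial, with selection directions and
# the prior weights used when weighted MGIDI is requested.
- {code: PH,   direction: maximize, weight: 0.4, units: cm}
- {code: LC,   direction: maximize, weight: 0.6, units: count}
- {code: INC,  direction: maximize, weight: 0.4, units: count}
- {code: INL,  direction: maximize, weight: 0.4, units: cm}
- {code: SD,   direction: maximize, weight: 0.7, units: cm}
- {code: LW,   direction: maximize, weight: 0.7, units: cm}
- {code: LL,   direction: maximize, weight: 0.7, units: cm}
- {code: PL,   direction: maximize, weight: 0.6, units: cm}
- {code: PDW,  direction: maximize, weight: 0.5, units: gr}
- {code: LWW,  direction: maximize, weight: 1.0, units: gr}
- {code: BRIX, direction: maximize, weight: 0.3, units: '%'}
- {code: SWW,  direction: maximize, weight: 1.0, units: gr}
- {code: GY,   direction: maximize, weight: 1.0, units: gr}
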