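# Typical clinical presentations used for occult-risk reporting: every level
# is observed, those listed under "involved" as metastatic, the rest healthy.
cN0:         {involved: []}
II:          {involved: [II]}
II+III:      {involved: [II, III]}
II+III+IV:   {involved: [II, III, IV]}
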