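# Literature sensitivity/specificity of diagnostic modalities for cervical
# nodal staging, used for consensus resolution and risk prediction.
CT:        {sensitivity: 0.81, specificity: 0.76}
PET:       {sensitivity: 0.79, specificity: 0.86}
MRI:       {sensitivity: 0.81, specificity: 0.63}
FNA:       {sensitivity: 0.80, specificity: 0.98}
pathology: {sensitivity: 1.00, specificity: 1.00}
consensus: {sensitivity: 1.00, specificity: 1.00}
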