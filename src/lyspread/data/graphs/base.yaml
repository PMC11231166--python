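# Minimal spread graph: tumor seeds every level; LNL-to-LNL arcs follow the
# main lymphatic drainage pathway II -> III -> IV.
tumor: [I, II, III, IV, V, VII]
I: []
II: [III]
III: [IV]
IV: []
V: []
VII: []
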