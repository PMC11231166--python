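# Evidence-maximizing spread graph: base graph plus I -> II and IV -> V.
tumor: [I, II, III, IV, V, VII]
I: [II]
II: [III]
III: [IV]
IV: [V]
V: []
VII: []
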