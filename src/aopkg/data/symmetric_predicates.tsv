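related_to
occurs_together_in_literature_with
associated_with
interacts_with
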