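occurs_together_in_literature_with	related_to
associated_with	related_to
genetically_associated_with	associated_with
affects	related_to
increases_expression_of	affects
increases_activity_of	affects
increases_response_to	affects
decreases_response_to	affects
causes	affects
participates_in	related_to
actively_involved_in	participates_in
has_participant	related_to
actively_involves	has_participant
interacts_with	related_to
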