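# Default CUIs treated as negation concepts when they co-occur with a
# significance concept in the same sentence ("Negative", "Negation",
# "Unchanged").  Editable.
C0205160  # Negative
C1518422  # Negation
C0442739  # Unchanged
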