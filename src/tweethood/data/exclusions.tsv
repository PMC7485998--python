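phrase
running late
walk away
run away
running behind
running out of
run out of
home run
walk me through
long run
in the long run
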