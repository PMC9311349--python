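Age group,Number of learners
Two-three years,4
Three-four years,8
Four-five years,12
Five-six years,5
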