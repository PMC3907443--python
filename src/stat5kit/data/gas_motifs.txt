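# Default GAS (gamma-activated sequence) motif set, one IUPAC pattern per
# line. The canonical STAT5 element is the 9-mer palindrome TTCNNNGAA.
TTCNNNGAA
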