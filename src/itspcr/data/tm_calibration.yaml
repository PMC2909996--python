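# Environmental constants for the shipped TmModel, obtained by
# calibrate_model() against the two anchor primers below (reference
# zero-mismatch Tm values for ITS1 and ITS4). Regenerate with:
#   itspcr tm --calibrate
salt_correction: owczarzy
monovalent_salt: 0.12758491788331613      # mol/L Na+ equivalents
strand_concentration: 2.1730661466948673e-09  # mol/L total strand (cT)
anchors:
  - name: ITS1
    sequence: TCCGTAGGTGAACCTGCGG
    tm: 58.64
  - name: ITS4
    sequence: TCCTCCGCTTATTGATATGC
    tm: 50.9
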