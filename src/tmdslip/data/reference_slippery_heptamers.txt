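# The 24 classical X XXY YYZ slippery heptamers: X any base, Y in {A,U},
# Z in {A,C,U}. Used to calibrate the slippery-classification cutoff.
AAAAAAA
AAAAAAC
AAAAAAU
AAAUUUA
AAAUUUC
AAAUUUU
CCCAAAA
CCCAAAC
CCCAAAU
CCCUUUA
CCCUUUC
CCCUUUU
GGGAAAA
GGGAAAC
GGGAAAU
GGGUUUA
GGGUUUC
GGGUUUU
UUUAAAA
UUUAAAC
UUUAAAU
UUUUUUA
UUUUUUC
UUUUUUU
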