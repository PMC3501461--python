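>synthetic_metacaspase_reference cys=150 his=90 synthetic stand-in reference domain
LQNEWQMLGNMKRQQDIYTGKEHCPHYQWMRLIQKANLWSVENMFLDVAWKMIWGEHWGI
AACPSAYGYLMLHGRHLTNHCHFITASFCHTRTGHPPWSAYLDSSNADGYMNGGYLGMTN
QAANVPDDQYQVAVMRIEWRHPTPTNDNGCSCNQMSSSCRINTMLCPNSASVEGVMTFYE
MPEALSWMGNFLFSYYHNWNSSYKFINPVEASWFQVWHMYGAKGIVVNGVMETYCEIFNA
HVPFRGSIKGPP
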