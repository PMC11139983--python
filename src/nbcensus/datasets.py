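"""Reference sequences for the VUN701-ACKR3 system.

These are the published sequences of the nanobody VUN701, the human
atypical chemokine receptor ACKR3 (UniProt P25106), and human CXCL12
(UniProt P48061), used as annotation references and worked examples.
"""

VUN701 = (
    "QVQLVESGGGLVQAGGSLRLSCAASGSTFSLHLMGWYRQAPGKQREVVATSGSGGDTNYADSVKGRFTIS"
    "RDNDKNTVDLQMNNLKPEDTADYYCRAQQKIGRDTFRDYWGQGTQVTVSS"
)

HACKR3 = (
    "MDLHLFDYSEPGNFSDISWPCNSSDCIVVDTVMCPNMPNKSVLLYTLSFIYIFIFVIGMIANSVVVWVNI"
    "QAKTTGYDTHCYILNLAIADLWVVLTIPVWVVSLVQHNQWPMGELTCKVTHLIFSINLFGSIFFLTCMSV"
    "DRYLSITYFTNTPSSRKKMVRRVVCILVWLLAFCVSLPDTYYLKTVTSASNNETYCRSFYPEHSIKEWLI"
    "GMELVSVVLGFAVPFSIIAVFYFLLARAISASSDQEKHSSRKIIFSYVVVFLVCWLPYHVAVLLDIFSIL"
    "HYIPFTCRLEHALFTALHVTQCLSLVHCCVNPVLYSFINRNYRYELMKAFIFKYSAKTGLTKLIDASRVS"
    "ETEYSALEQSTK"
)

HCXCL12 = "KPVSLSYRCPCRFFESHVARANVKHLKILNTPNCALQIVARLKNNNRQVCIDPKLKWIQEYLEKALNK"
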