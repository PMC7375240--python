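>RhoA fragment 99-118; other rows are synthetic family stand-ins
WTPEVKHFCPNVPIILVGNK
>KRas_like synthetic
WTPEVKHSVPNVPMVLVGNK
>Rab7_like synthetic
WSPEVKHAAPNVPIILIGNK
>Ran_like synthetic
WTADVKHLTPNVPIVLVGNK
>Arf1_like synthetic
FSPEVKHVQPNVPLLLLGNK
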