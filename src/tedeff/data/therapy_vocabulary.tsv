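raw	therapy_class
Alferon	immunotherapy
GM-CSF	immunotherapy
IL-18	immunotherapy
IL-2	immunotherapy
IL2	immunotherapy
interferon	immunotherapy
Interferon-?2	immunotherapy
Interferon-alfa	immunotherapy
Interferon alfa	immunotherapy
Interferon alfa-2b	immunotherapy
interferon alpha	immunotherapy
Interleukin-2	immunotherapy
Interleukin – 2	immunotherapy
Laferon	immunotherapy
Leukine	immunotherapy
Alpha Interferon	immunotherapy
IFN-Alpha (Intron)	immunotherapy
IL-2 (high dose)	immunotherapy
IL-2 Thearpy (interleukin)	immunotherapy
INF	immunotherapy
interferon-alpha	immunotherapy
interleukin-2	immunotherapy
Interleukin 2-high dose	immunotherapy
Intron A	immunotherapy
Proleukin	immunotherapy
proleukin (IL-2)	immunotherapy
ipilimumab	checkpoint
Yervoy	checkpoint
pembrolizumab	checkpoint
nivolumab	checkpoint
Sunitinib	targeted
Sorafenib	targeted
Pazopanib	targeted
Bevacizumab	targeted
Temsirolimus	targeted
Everolimus	targeted
Axitinib	targeted
Vemurafenib	targeted
Dabrafenib	targeted
Trametinib	targeted
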