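verbatim_name,substance,class
NIVOLUMAB,nivolumab,anti-PD-1
OPDIVO,nivolumab,anti-PD-1
PEMBROLIZUMAB,pembrolizumab,anti-PD-1
KEYTRUDA,pembrolizumab,anti-PD-1
CEMIPLIMAB,cemiplimab,anti-PD-1
CEMIPLIMAB-RWLC,cemiplimab,anti-PD-1
LIBTAYO,cemiplimab,anti-PD-1
ATEZOLIZUMAB,atezolizumab,anti-PD-L1
TECENTRIQ,atezolizumab,anti-PD-L1
AVELUMAB,avelumab,anti-PD-L1
BAVENCIO,avelumab,anti-PD-L1
DURVALUMAB,durvalumab,anti-PD-L1
IMFINZI,durvalumab,anti-PD-L1
IPILIMUMAB,ipilimumab,anti-CTLA-4
YERVOY,ipilimumab,anti-CTLA-4
TREMELIMUMAB,tremelimumab,anti-CTLA-4
TREMELIMUMAB-ACTL,tremelimumab,anti-CTLA-4
IMJUDO,tremelimumab,anti-CTLA-4
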