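analyte,units,commercial,developed
direct-bilirubin,mg/dL,0.52,0.55
direct-bilirubin,mg/dL,2.13,2.20
direct-bilirubin,mg/dL,8.25,8.89
direct-bilirubin,mg/dL,12.45,12.90
direct-bilirubin,mg/dL,17.1,17.60
total-bilirubin,mg/dL,0.32,0.35
total-bilirubin,mg/dL,3.47,3.78
total-bilirubin,mg/dL,9.55,10.1
total-bilirubin,mg/dL,14.25,14.8
total-bilirubin,mg/dL,18.41,19.21
ALT,U/L,15.14,15.7
ALT,U/L,74.58,79.3
ALT,U/L,105.24,110
ALT,U/L,178.77,183.5
ALT,U/L,225.25,230
AST,U/L,20.15,21.78
AST,U/L,62.25,66.9
AST,U/L,124.47,129.2
AST,U/L,166.66,171.4
AST,U/L,280.24,284.9
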