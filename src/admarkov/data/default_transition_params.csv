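from,to,mean,sd
CN,MCI,0.0432,0.0055
CN,WITHDRAWN,0.0372,0.0046
MCI,CN,0.0218,0.0044
MCI,AD,0.0954,0.0090
MCI,WITHDRAWN,0.0528,0.0057
AD,WITHDRAWN,0.1765,0.0127
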