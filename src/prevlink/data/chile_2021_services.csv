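health_service,population,school_adjusted_prev_pct,ci_low_pct,ci_high_pct
Aconcagua,46840,0.43,0.37,0.5
Aisén,19890,0.75,0.63,0.9
Antofagasta,119378,0.83,0.77,0.88
Araucanía Norte,36651,0.3,0.24,0.38
Araucanía Sur,132242,0.37,0.34,0.41
Arauco,31318,0.72,0.62,0.82
Arica,44609,0.61,0.54,0.7
Atacama,58743,0.31,0.27,0.37
Biobío,71411,0.42,0.37,0.47
Chiloé,30908,0.43,0.36,0.52
Concepción,109502,0.77,0.72,0.83
Coquimbo,141152,0.4,0.36,0.43
Iquique,69935,0.43,0.38,0.49
Magallanes,28031,0.83,0.72,0.96
Maule,182352,0.3,0.28,0.33
Metropolitano Central,122576,0.42,0.38,0.46
Metropolitano Norte,180230,0.29,0.26,0.31
Metropolitano Occidente,277282,0.34,0.32,0.36
Metropolitano Oriente,182798,0.3,0.27,0.33
Metropolitano Sur,200984,0.4,0.37,0.43
Metropolitano Sur Oriente,236817,0.36,0.34,0.39
O'Higgins,161335,0.42,0.39,0.46
Osorno,40266,0.43,0.37,0.51
Reloncaví,79767,0.42,0.37,0.47
Talcahuano,54678,0.81,0.74,0.9
Valdivia,66206,0.3,0.26,0.35
Valparaíso,78598,0.68,0.62,0.74
Viña del Mar,172456,0.66,0.62,0.7
Ñuble,79351,1.29,1.21,1.37
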