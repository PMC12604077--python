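tissue,reference,year,sequence,te_ms,field,mi_mm,mi_tcr,gly_mm,gly_tcr,mi_gly
gray,Schulte and Boesiger,2006,2DJ,31-229,3T,,0.99,,0.12,8.0
gray,Prescot et al.,2006,TEavg,30-284,4T,,,,0.03,
gray,Choi et al.,2008,Triple_ref,198,3T,5.80,,0.50,,11.6
gray,Gambarota et al.,2009,SPECIAL,30,7T,,0.61,,0.14,4.4
gray,Banerjee et al.,2012,PRESS,150,7T,6.90,,1.10,,6.3
gray,Marjanska et al.,2012,LASER,35,7T,6.40,,0.70,,9.1
gray,Li et al.,2015,MRSI,30,7T,,0.61,,0.17,3.6
gray,Ganji et al.,2016,MRSI,160,3T,10.20,,1.10,,9.3
gray,Murali-Manohar et al.,2020,semi-LASER,24-60,9.4T,5.22,,1.11,,4.7
white,Hofmann et al.,2002,PRESS,20,1.5T,4.53,,0.48,,9.4
white,Banerjee et al.,2012,PRESS,150,7T,1.60,,0.10,,16.0
white,Li et al.,2015,MRSI,30,7T,,0.66,,0.20,3.3
white,Ganji et al.,2016,MRSI,160,3T,5.70,,0.30,,19.0
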