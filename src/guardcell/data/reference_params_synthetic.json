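{
 "alpha10": 97.95416348093994,
 "alpha11": 39.44631725129906,
 "alpha12": 48.122187978831526,
 "k11": 6.040574168656142,
 "k12": 8.489875762200095,
 "beta11": 0.009999999999970642,
 "beta12": 0.9171903373385791,
 "alpha20": 0.0010000108409252315,
 "alpha21": 19.569133883266147,
 "alpha22": 7.127311182261358,
 "k21": 66.90121882736508,
 "k22": 3.5776191592970843,
 "n1": 2.0,
 "alpha23": 0.018018018018018018,
 "beta20": 0.0018772734772496936,
 "n2": 2.0,
 "beta13": 0.16666666666666666,
 "alpha31": 99.999997511933,
 "alpha32": 2.0444177325630326,
 "k31": 999.9999991099206,
 "beta30": 0.3013737451673396,
 "alpha40": 0.0010000019869707045,
 "alpha41": 9.001005779837413,
 "alpha42": 0.8410432394831008,
 "beta40": 0.06119414104088602,
 "alpha43": 0.0,
 "alpha51": 1214.7510174070353,
 "k51": 0.01000006416104064,
 "beta50": 0.0008345332251118933
}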