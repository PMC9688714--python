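tissue	condition	position	replicate	edited	total
microglia	naive	2:122152740	1	1	10
microglia	naive	2:122152740	2	1	10
microglia	naive	2:122152740	3	0	10
microglia	naive	2:122152740	4	0	10
microglia	naive	2:122152742	1	1	10
microglia	naive	2:122152742	2	0	10
microglia	naive	2:122152742	3	0	10
microglia	naive	2:122152742	4	0	10
microglia	naive	2:122152871	1	1	10
microglia	naive	2:122152871	2	1	10
microglia	naive	2:122152871	3	0	10
microglia	naive	2:122152871	4	0	10
microglia	naive	2:naive_nd1	1	0	10
microglia	naive	2:naive_nd1	2	0	10
microglia	naive	2:naive_nd1	3	0	10
microglia	naive	2:naive_nd1	4	0	10
microglia	naive	2:naive_nd2	1	0	10
microglia	naive	2:naive_nd2	2	0	10
microglia	naive	2:naive_nd2	3	0	10
microglia	naive	2:naive_nd2	4	0	10
microglia	naive	2:naive_nd3	1	0	10
microglia	naive	2:naive_nd3	2	0	10
microglia	naive	2:naive_nd3	3	0	10
microglia	naive	2:naive_nd3	4	0	10
microglia	acute	2:122152682	1	1	20
microglia	acute	2:122152682	2	1	20
microglia	acute	2:122152682	3	1	20
microglia	acute	2:122152682	4	0	20
microglia	acute	2:122152687	1	1	20
microglia	acute	2:122152687	2	0	20
microglia	acute	2:122152687	3	0	20
microglia	acute	2:122152687	4	0	20
microglia	acute	2:122152707	1	1	20
microglia	acute	2:122152707	2	0	20
microglia	acute	2:122152707	3	0	20
microglia	acute	2:122152707	4	0	20
microglia	acute	2:122152740	1	1	20
microglia	acute	2:122152740	2	1	20
microglia	acute	2:122152740	3	1	20
microglia	acute	2:122152740	4	1	20
microglia	acute	2:122152742	1	1	20
microglia	acute	2:122152742	2	1	20
microglia	acute	2:122152742	3	1	20
microglia	acute	2:122152742	4	0	20
microglia	acute	2:122152751	1	1	20
microglia	acute	2:122152751	2	0	20
microglia	acute	2:122152751	3	0	20
microglia	acute	2:122152751	4	0	20
microglia	acute	2:122152871	1	1	20
microglia	acute	2:122152871	2	1	20
microglia	acute	2:122152871	3	1	20
microglia	acute	2:122152871	4	0	20
microglia	acute	2:122152912	1	1	20
microglia	acute	2:122152912	2	0	20
microglia	acute	2:122152912	3	0	20
microglia	acute	2:122152912	4	0	20
microglia	acute	2:122152928	1	1	20
microglia	acute	2:122152928	2	0	20
microglia	acute	2:122152928	3	0	20
microglia	acute	2:122152928	4	0	20
microglia	acute	2:acute_nd1	1	0	20
microglia	acute	2:acute_nd1	2	0	20
microglia	acute	2:acute_nd1	3	0	20
microglia	acute	2:acute_nd1	4	0	20
microglia	acute	2:acute_nd2	1	0	20
microglia	acute	2:acute_nd2	2	0	20
microglia	acute	2:acute_nd2	3	0	20
microglia	acute	2:acute_nd2	4	0	20
microglia	acute	2:acute_nd3	1	0	20
microglia	acute	2:acute_nd3	2	0	20
microglia	acute	2:acute_nd3	3	0	20
microglia	acute	2:acute_nd3	4	0	20
microglia	acute	2:acute_nd4	1	0	20
microglia	acute	2:acute_nd4	2	0	20
microglia	acute	2:acute_nd4	3	0	20
microglia	acute	2:acute_nd4	4	0	20
microglia	acute	2:acute_nd5	1	0	20
microglia	acute	2:acute_nd5	2	0	20
microglia	acute	2:acute_nd5	3	0	20
microglia	acute	2:acute_nd5	4	0	20
microglia	acute	2:acute_nd6	1	0	20
microglia	acute	2:acute_nd6	2	0	20
microglia	acute	2:acute_nd6	3	0	20
microglia	acute	2:acute_nd6	4	0	20
microglia	acute	2:acute_nd7	1	0	20
microglia	acute	2:acute_nd7	2	0	20
microglia	acute	2:acute_nd7	3	0	20
microglia	acute	2:acute_nd7	4	0	20
microglia	acute	2:acute_nd8	1	0	20
microglia	acute	2:acute_nd8	2	0	20
microglia	acute	2:acute_nd8	3	0	20
microglia	acute	2:acute_nd8	4	0	20
microglia	acute	2:acute_nd9	1	0	20
microglia	acute	2:acute_nd9	2	0	20
microglia	acute	2:acute_nd9	3	0	20
microglia	acute	2:acute_nd9	4	0	20
microglia	acute	2:acute_nd10	1	0	20
microglia	acute	2:acute_nd10	2	0	20
microglia	acute	2:acute_nd10	3	0	20
microglia	acute	2:acute_nd10	4	0	20
brain	naive	2:122152687	1	1	30
brain	naive	2:122152687	2	0	30
brain	naive	2:122152687	3	0	30
brain	naive	2:122152707	1	1	30
brain	naive	2:122152707	2	0	30
brain	naive	2:122152707	3	0	30
brain	naive	2:122152787	1	1	30
brain	naive	2:122152787	2	0	30
brain	naive	2:122152787	3	0	30
brain	acute	2:122152682	1	1	30
brain	acute	2:122152682	2	0	30
brain	acute	2:122152682	3	0	30
brain	acute	2:122152694	1	1	30
brain	acute	2:122152694	2	0	30
brain	acute	2:122152694	3	0	30
brain	acute	2:122152740	1	1	30
brain	acute	2:122152740	2	1	30
brain	acute	2:122152740	3	1	30
brain	acute	2:122152742	1	1	30
brain	acute	2:122152742	2	0	30
brain	acute	2:122152742	3	0	30
brain	acute	2:122152745	1	1	30
brain	acute	2:122152745	2	0	30
brain	acute	2:122152745	3	0	30
brain	acute	2:122152751	1	1	30
brain	acute	2:122152751	2	0	30
brain	acute	2:122152751	3	0	30
brain	acute	2:122152759	1	1	30
brain	acute	2:122152759	2	0	30
brain	acute	2:122152759	3	0	30
brain	acute	2:122152763	1	1	30
brain	acute	2:122152763	2	1	30
brain	acute	2:122152763	3	0	30
brain	acute	2:122152845	1	1	30
brain	acute	2:122152845	2	0	30
brain	acute	2:122152845	3	0	30
brain	acute	2:122152871	1	1	30
brain	acute	2:122152871	2	1	30
brain	acute	2:122152871	3	1	30
brain	acute	2:122152928	1	1	30
brain	acute	2:122152928	2	1	30
brain	acute	2:122152928	3	0	30
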