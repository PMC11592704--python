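variant	cohort_alt	cohort_total	cohort_hom	gnomAD_alt	gnomAD_total	gnomAD_hom	TurkishVariome_alt	TurkishVariome_total	TurkishVariome_hom
V1	18	3414	0	644	1,595,894	1	13	5330	0
V2	8	3414	0	4458	1,614,104	37	17	7958	1
V3	4	3414	1	41	1,428,834	NA	NA	NA	NA
V4	2	3414	0	39	1,613,212	0	1	7958	0
V5	1	3414	0	NA	NA	NA	NA	NA	NA
V6	2	3414	0	NA	NA	NA	NA	NA	NA
V7	2	3414	0	3467	1,611,346	5	1	7148	0
V8	1	3414	0	5	1,613,818	0	1	7472	0
V9	1	3414	0	102	1,613,966	0	NA	NA	NA
V10	3	3414	0	48	1,614,058	0	1	7958	0
V11	1	3414	0	32	1,614,006	0	3	7958	0
V12	2	3414	0	NA	NA	NA	NA	NA	NA
V13	1	3414	0	1	1,555,852	0	NA	NA	NA
V14	1	3414	0	NA	NA	NA	1	7958	0
V15	1	3414	0	16	1,556,040	0	2	5386	0
V16	1	3414	0	2	1,614,146	0	NA	NA	NA
V17	5	3414	0	7	1,612,796	0	5	7958	0
V18	1	3414	0	10	1,613,718	0	3	7458	0
V19	1	3414	0	73	1,596,022	0	NA	NA	NA
V20	1	3414	0	3	1,613,708	0	NA	NA	NA
V21	13	3414	0	606	1,613,498	3	28	7398	0
V22	1	3414	0	186	1,613,932	0	16	7958	0
V23	1	3414	0	72	1,595,990	0	NA	NA	NA
V24	13	3414	1	103	1,614,166	0	14	7958	0
V25	3	3414	0	205	1,595,820	0	4	5298	0
V26	1	3414	0	208	1,613,948	0	3	7958	0
V27	1	3414	0	14	1,437,854	1	6	7954	0
V28	1	3414	0	1	1,613,862	0	2	7958	0
V29	4	3414	0	105	1,613,522	0	5	7958	0
V30	1	3414	0	1	1,450,494	0	NA	NA	NA
V31	1	3414	0	23	1,595,222	0	NA	NA	NA
V32	10	3414	0	24	1,613,866	0	5	7958	0
V33	1	3414	0	2	1,613,974	0	NA	NA	NA
V34	12	3414	0	14	1,613,880	0	NA	NA	NA
V35	1	3414	0	3	1,613,088	0	2	7958	0
V36	1	3414	0	35	1,594,568	0	1	5390	0
V37	1	3414	0	2	1,613,664	0	NA	NA	NA
V38	1	3414	0	1337	1,613,844	0	1	7958	0
V39	1	3414	0	1	1,608,334	0	NA	NA	NA
V40	1	3414	0	2	1,613,500	0	1	7370	0
V41	3	3414	0	5	1,614,184	0	NA	NA	NA
V42	1	3414	0	1	1,554,814	0	NA	NA	NA
V43	1	3414	0	NA	NA	NA	NA	NA	NA
V44	1	3414	0	NA	NA	NA	NA	NA	NA
V45	1	3414	0	NA	NA	NA	NA	NA	NA
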