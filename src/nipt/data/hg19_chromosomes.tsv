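chrom	length	gc
chr1	249250621	0.417
chr2	243199373	0.402
chr3	198022430	0.397
chr4	191154276	0.383
chr5	180915260	0.395
chr6	171115067	0.396
chr7	159138663	0.408
chr8	146364022	0.402
chr9	141213431	0.413
chr10	135534747	0.416
chr11	135006516	0.416
chr12	133851895	0.408
chr13	115169878	0.385
chr14	107349540	0.409
chr15	102531392	0.422
chr16	90354753	0.448
chr17	81195210	0.455
chr18	78077248	0.398
chr19	59128983	0.484
chr20	63025520	0.441
chr21	48129895	0.409
chr22	51304566	0.480
chrX	155270560	0.395
chrY	59373566	0.391
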