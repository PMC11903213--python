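path	read_id	identity_pct	alignment_bp	ref_start	ref_end	read_start	read_end
ctg1-R1-ctg2	562c7825-9e7e-4ee8-b743-629e0c5429e0	94.231	11977	1	11782	20947	9194
ctg1-R1-ctg2	1151f81d-0d93-4347-906d-d2a948e02643	97.768	11603	252	11784	26709	15213
ctg3-R1-ctg3	2286ff3b-1bcf-484e-8d90-a9f0fc049c2c	96.615	11907	1	11784	25444	13695
ctg3-R1-ctg3	3cc576dd-d502-4e1b-993e-5d1a8a2b664a	91.94	10633	1351	11784	15543	5203
ctg3-R1-ctg3	b730da28-53be-40f1-8696-93ad05af9df7	92.45	9695	761	10352	1	9210
ctg2-R2-ctg1	6c784803-80c8-418f-9875-8a61fa70a442	95.546	7589	1	7519	1280	8722
ctg2-R2-ctg1	2b3fb0ce-2925-43d1-b629-bdc159c94af4	94.706	5837	1089	6858	1	5718
ctg4-R2-ctg4	b23bc2dc-f634-42a7-a5a4-4fce6ea8ea2b	88.29	7737	1	7518	17324	9867
ctg4-R2-ctg4	45ed6141-ce33-459f-b9c0-7abb14d59bb9	84.447	7722	26	7519	21420	14093
ctg4-R2-ctg4	2652d0ea-c9ef-40fc-8afb-00c9138a3b8f	92.389	7660	1	7519	8225	772
ctg4-R2-ctg4	c620907e-5bd2-4d9d-b0e7-1e0c9caaa892	92.478	7658	1	7519	8512	1055
ctg4-R2-ctg4	0edb2542-3667-427c-a802-8bc9fe1fc5e3	97.11	7578	1	7519	8470	15959
ctg4-R2-ctg4	562afc1c-6b1f-47d5-a0a8-d376cd34e362	96.808	7363	213	7519	18473	25742
ctg2-R2-ctg4	c4604840-5506-41df-921a-1625836b610a	97.676	7572	1	7519	10027	2525
ctg2-R2-ctg4	81dc97e4-9b4f-42f5-a6bc-3ed9c41cce8a	96.139	7433	1	7375	7336	6
ctg2-R2-ctg4	804e0dd3-25c6-40ff-b219-53ea20270aa7	88.613	6077	1235	7159	5887	1
ctg4-R2-ctg1	5da75316-8aa7-455b-8a7e-0b24b33339f6	89.496	7711	1	7519	56423	49073
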