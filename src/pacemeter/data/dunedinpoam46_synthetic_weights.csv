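# SYNTHETIC stand-in weight table: same structure as the published
# 46-CpG pace-of-aging methylation model (one (Intercept) row plus 46
# CpG weights), with randomly generated probe ids and weights. It is
# NOT the published model; replace with the real coefficient file to
# score real arrays.
probe,weight
(Intercept),-1.151373
cg00707146,-0.144465
cg01517548,0.177118
cg05517228,0.676156
cg05554042,0.411203
cg06646993,-0.385358
cg07722679,0.338874
cg08494678,-0.152808
cg10505916,-0.04356
cg13775467,-0.116139
cg16264067,0.108109
cg18110256,0.593088
cg18992425,-0.343034
cg21939210,0.300667
cg23466600,0.026966
cg23798195,0.284848
cg24698929,0.297646
cg24897015,-0.03764
cg25168512,0.235966
cg26771646,0.429914
cg27256975,-0.390852
cg32288345,0.4556
cg32608868,0.118197
cg32680932,0.538968
cg34378055,-0.722817
cg39009466,-0.012528
cg45902109,-0.169271
cg47875358,-0.231365
cg49914664,-0.675239
cg50114058,-0.087391
cg50262568,-0.09594
cg51144351,-0.398387
cg51504113,-0.321506
cg54925200,0.269892
cg57213103,-0.057273
cg62185048,0.357871
cg62366783,0.751594
cg62416872,0.001937
cg62922976,-0.011589
cg63829352,-0.559138
cg68094533,-0.712468
cg72538548,-0.096537
cg73035918,-0.260924
cg73382678,0.217214
cg74850771,0.34
cg76630646,-0.089618
cg77290273,0.11362
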