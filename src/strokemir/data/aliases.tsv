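reported_name	canonical_name
hsa-let-7e-5p	hsa-let-7e-5p
hsa-let-7f-5p	hsa-let-7f-5p
hsa-let-7i-5p	hsa-let-7i-5p
hsa-miR-106b-5p	hsa-miR-106b-5p
hsa-miR-122-5p	hsa-miR-122-5p
hsa-miR-1229-3p	hsa-miR-1229-3p
hsa-miR-1238-5p	hsa-miR-1238-5p
hsa-miR-124	hsa-miR-124-3p
hsa-miR-124-3p	hsa-miR-124-3p
hsa-miR-1246	hsa-miR-1246
hsa-miR-126-3p	hsa-miR-126-3p
hsa-miR-1270	hsa-miR-1270
hsa-miR-1275	hsa-miR-1275
hsa-miR-128-3p	hsa-miR-128-3p
hsa-miR-1294	hsa-miR-1294
hsa-miR-1299	hsa-miR-1299
hsa-miR-1301-3p	hsa-miR-1301-3p
hsa-miR-130a-3p	hsa-miR-130a-3p
hsa-miR-140-5p	hsa-miR-140-5p
hsa-miR-142-3p	hsa-miR-142-3p
hsa-miR-144-3p	hsa-miR-144-3p
hsa-miR-145-5p	hsa-miR-145-5p
hsa-miR-146a-5p	hsa-miR-146a-5p
hsa-miR-146b-5p	hsa-miR-146b-5p
hsa-miR-148a-3p	hsa-miR-148a-3p
hsa-miR-149-5p	hsa-miR-149-5p
hsa-miR-15a-5p	hsa-miR-15a-5p
hsa-miR-16-5p	hsa-miR-16-5p
hsa-miR-17-5p	hsa-miR-17-5p
hsa-miR-185	hsa-miR-185-5p
hsa-miR-185-5p	hsa-miR-185-5p
hsa-miR-186-5p	hsa-miR-186-5p
hsa-miR-18b-5p	hsa-miR-18b-5p
hsa-miR-1913	hsa-miR-1913
hsa-miR-195-5p	hsa-miR-195-5p
hsa-miR-19a-3p	hsa-miR-19a-3p
hsa-miR-20b-5p	hsa-miR-20b-5p
hsa-miR-21-5p	hsa-miR-21-5p
hsa-miR-210-3p	hsa-miR-210-3p
hsa-miR-211-5p	hsa-miR-211-5p
hsa-miR-218	hsa-miR-218-5p
hsa-miR-218-5p	hsa-miR-218-5p
hsa-miR-219-5p	hsa-miR-218-5p
hsa-miR-22-3p	hsa-miR-22-3p
hsa-miR-221-3p	hsa-miR-221-3p
hsa-miR-222	hsa-miR-222-3p
hsa-miR-222-3p	hsa-miR-222-3p
hsa-miR-223-3p	hsa-miR-223-3p
hsa-miR-224-3p	hsa-miR-224-3p
hsa-miR-23a-3p	hsa-miR-23a-3p
hsa-miR-27b-3p	hsa-miR-27b-3p
hsa-miR-301a-3p	hsa-miR-301a-3p
hsa-miR-30a-5p	hsa-miR-30a-5p
hsa-miR-30d-5p	hsa-miR-30d-5p
hsa-miR-3149	hsa-miR-3149
hsa-miR-32-3p	hsa-miR-32-3p
hsa-miR-32-5p	hsa-miR-32-5p
hsa-miR-320a	hsa-miR-320a
hsa-miR-320a-3p	hsa-miR-320a
hsa-miR-320d	hsa-miR-320d
hsa-miR-320e	hsa-miR-320e
hsa-miR-330-3p	hsa-miR-330-3p
hsa-miR-335-5p	hsa-miR-335-5p
hsa-miR-33a-5p	hsa-miR-33a-5p
hsa-miR-340-5p	hsa-miR-340-5p
hsa-miR-34a-5p	hsa-miR-34a-5p
hsa-miR-362-3p	hsa-miR-362-3p
hsa-miR-363-3p	hsa-miR-363-3p
hsa-miR-376c-3p	hsa-miR-376c-3p
hsa-miR-377-5p	hsa-miR-377-5p
hsa-miR-378a-5p	hsa-miR-378a-5p
hsa-miR-379-5p	hsa-miR-379-5p
hsa-miR-382-5p	hsa-miR-382-5p
hsa-miR-411-5p	hsa-miR-411-5p
hsa-miR-423-5p	hsa-miR-423-5p
hsa-miR-424-5p	hsa-miR-424-5p
hsa-miR-4306	hsa-miR-4306
hsa-miR-432-5p	hsa-miR-432-5p
hsa-miR-4429	hsa-miR-4429
hsa-miR-4446-3p	hsa-miR-4446-3p
hsa-miR-451a	hsa-miR-451a
hsa-miR-4656	hsa-miR-4656
hsa-miR-4739	hsa-miR-4739
hsa-miR-485-3p	hsa-miR-485-3p
hsa-miR-487	hsa-miR-487b-3p
hsa-miR-487b	hsa-miR-487b-3p
hsa-miR-487b-3p	hsa-miR-487b-3p
hsa-miR-503-5p	hsa-miR-503-5p
hsa-miR-505-5p	hsa-miR-505-5p
hsa-miR-517b-3p	hsa-miR-517b-3p
hsa-miR-518b	hsa-miR-518b
hsa-miR-532-5p	hsa-miR-532-5p
hsa-miR-544a	hsa-miR-544a
hsa-miR-574-5p	hsa-miR-574-5p
hsa-miR-579-3p	hsa-miR-579-3p
hsa-miR-628-5p	hsa-miR-628-5p
hsa-miR-660-5p	hsa-miR-660-5p
hsa-miR-664a-5p	hsa-miR-664a-5p
hsa-miR-6721-5p	hsa-miR-6721-5p
hsa-miR-676-3p	hsa-miR-676-3p
hsa-miR-874-3p	hsa-miR-874-3p
hsa-miR-877-5p	hsa-miR-877-5p
hsa-miR-9	hsa-miR-9-5p
hsa-miR-9-5p	hsa-miR-9-5p
hsa-miR-93-5p	hsa-miR-93-5p
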